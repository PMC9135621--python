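"""Group-level inference on contrast maps.

One-sample t-maps across participants, conversion to z-maps, cluster-extent
family-wise-error control via a sign-flipping permutation null of the
maximum cluster size, ROI mean extraction, and one-way repeated-measures
ANOVA with BH-FDR adjustment across an ROI family.

Candidate clusters are formed by a two-tailed cluster-defining threshold
(default |z| > 3.29, i.e. two-tailed p < 0.001), labelling positive and
negative suprathreshold voxels separately with face (6-neighbour)
connectivity.  Cluster-level corrected p-values come from the permutation
distribution of the largest cluster (over both signs), which controls FWE
without Gaussian-random-field assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .maps import ConnectivityMap, StatMap
from .utils import check_same_grid

DEFAULT_PERMUTATION_SEED = 20220414


def two_tailed_z_quantile(p: float) -> float:
    """|z| cutoff with two-tailed tail mass ``p`` (p = 0.001 -> 3.29)."""
    if not (0 < p < 1):
        raise ValidationError("p must be in (0, 1)")
    return float(stats.norm.isf(p / 2.0))


def one_sample_t_map(maps: Sequence[ConnectivityMap]) -> StatMap:
    """Voxelwise one-sample t across participants: t = mean / (sd / sqrt(n)).

    Voxels with zero across-participant SD (or any non-finite value) are
    masked out of the statistic map.
    """
    maps = list(maps)
    n = len(maps)
    if n < 2:
        raise ValidationError("one_sample_t_map requires at least 2 participants")
    check_same_grid([m.data for m in maps])
    X = np.stack([m.data for m in maps])  # (n, x, y, z)
    finite = np.all(np.isfinite(X), axis=0)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    valid = finite & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(data=t, statistic="t", df=n - 1, n=n, mask=valid, affine=maps[0].affine)


def t_to_z(t, df: int):
    """Map t-values to standard-normal z-values preserving tail probability.

    ``z = Phi^{-1}(F_t(t; df))`` evaluated through log tail probabilities
    (``t.logsf`` composed with ``ndtri_exp``) so extreme t-values convert
    without underflow; odd in t by construction.  Non-finite input
    propagates as NaN.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    z = np.full(t_arr.shape, np.nan)
    ok = np.isfinite(t_arr)
    with np.errstate(divide="ignore"):
        log_tail = stats.t.logsf(np.abs(t_arr[ok]), df)
    magnitude = -special.ndtri_exp(log_tail)
    z[ok] = np.sign(t_arr[ok]) * magnitude
    return float(z[0]) if scalar else z


def z_map_from_t(tmap: StatMap) -> StatMap:
    z = t_to_z(tmap.data, tmap.df)
    return StatMap(
        data=np.asarray(z), statistic="z", df=None, n=tmap.n, mask=tmap.mask, affine=tmap.affine
    )


# ---------------------------------------------------------------------------
# Cluster-extent inference
# ---------------------------------------------------------------------------

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterTable:
    """Candidate clusters with sizes, peaks, and corrected p-values."""

    table: pd.DataFrame  # cluster_id, sign, size, peak_z, peak_i/j/k, p_fwe, significant
    labels: np.ndarray   # 3D int array; 0 = background, ids contiguous from 1
    cdt: float
    alpha: float
    n_perm: int

    def __len__(self):
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_labels(self) -> np.ndarray:
        keep = set(self.table.loc[self.table["significant"], "cluster_id"])
        out = np.where(np.isin(self.labels, list(keep)), self.labels, 0)
        return out


def _label_candidates(z: np.ndarray, cdt: float, structure: np.ndarray):
    """Label positive and negative suprathreshold voxels separately.

    Returns a combined label volume with contiguous ids and a list of
    (id, sign, size, peak_z, peak_index) tuples.
    """
    z_safe = np.where(np.isfinite(z), z, 0.0)
    labels = np.zeros(z.shape, dtype=np.int32)
    records = []
    next_id = 1
    for sign, supra in ((1, z_safe > cdt), (-1, z_safe < -cdt)):
        lab, n = ndimage.label(supra, structure=structure)
        for cid in range(1, n + 1):
            voxels = lab == cid
            size = int(voxels.sum())
            vals = z_safe[voxels]
            peak_pos = np.argmax(np.abs(vals))
            peak_z = float(vals[peak_pos])
            idx = np.argwhere(voxels)[peak_pos]
            labels[voxels] = next_id
            records.append((next_id, sign, size, peak_z, tuple(int(i) for i in idx)))
            next_id += 1
    return labels, records


def _max_null_cluster_sizes(
    X: np.ndarray,
    mask_flat: np.ndarray,
    grid: tuple,
    t_cdt: float,
    n_perm: int,
    structure: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation null of the maximum cluster size under sign flipping.

    ``X`` is (n, V_masked).  Sum of squares is sign-invariant, so every
    permutation t-map needs only the flipped mean, making the null cheap to
    evaluate exactly as the observed statistic is computed.
    """
    n = X.shape[0]
    sumsq = np.sum(X**2, axis=0)
    maxima = np.zeros(n_perm, dtype=np.int64)
    batch = 100
    vol = np.zeros(grid)
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        signs = rng.choice([-1.0, 1.0], size=(b, n))
        M = signs @ X / n  # (b, V)
        var = (sumsq - n * M**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = np.where(var > 0, M / np.sqrt(var / n), 0.0)
        supra = np.abs(tperm) > t_cdt
        counts = supra.sum(axis=1)
        for j in range(b):
            if counts[j] == 0:
                continue
            vol[...] = 0.0
            vol.reshape(-1)[mask_flat] = tperm[j]
            m = 0
            for s_mask in (vol > 0, vol < 0):
                hit = s_mask & (np.abs(vol) > t_cdt)
                if hit.any():
                    lab, ncl = ndimage.label(hit, structure=structure)
                    if ncl:
                        m = max(m, int(np.bincount(lab.ravel())[1:].max()))
            maxima[start + j] = m
    return maxima


def cluster_threshold(
    zmap: StatMap,
    contrast_maps: Sequence[ConnectivityMap],
    cdt: float = 3.29,
    alpha: float = 0.05,
    n_perm: int = 500,
    connectivity: int = 6,
    seed: Optional[int] = DEFAULT_PERMUTATION_SEED,
) -> ClusterTable:
    """Two-tailed cluster-extent inference with permutation FWE correction.

    Suprathreshold voxels (|z| > ``cdt``) are labelled by the requested
    neighbourhood (6 faces by default); each candidate cluster's corrected
    p-value is the proportion of sign-flipping permutations (plus the
    identity) whose maximum cluster size reaches the candidate's size.
    Clusters with corrected p < ``alpha`` are marked significant.
    """
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be one of 6, 18, 26")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if 1.0 / (n_perm + 1) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve corrected p below {1.0 / (n_perm + 1):.4f}; "
            "proceeding",
            stacklevel=2,
        )
    structure = _STRUCTURES[connectivity]
    grid = zmap.grid
    labels, records = _label_candidates(zmap.data, cdt, structure)

    columns = ["cluster_id", "sign", "size", "peak_z", "peak_i", "peak_j", "peak_k", "p_fwe", "significant"]
    if not records:
        empty = pd.DataFrame(columns=columns)
        return ClusterTable(table=empty, labels=labels, cdt=cdt, alpha=alpha, n_perm=n_perm)

    maps = list(contrast_maps)
    check_same_grid([m.data for m in maps] + [zmap.data])
    n = len(maps)
    if n < 2:
        raise ValidationError("cluster_threshold requires >= 2 contrast maps for the null")
    # Work in t-space: the z CDT maps monotonically to a t CDT for this df.
    df = n - 1
    t_cdt = float(stats.t.isf(stats.norm.sf(cdt), df))
    X4 = np.stack([m.data for m in maps])
    mask = np.all(np.isfinite(X4), axis=0)
    if zmap.mask is not None:
        mask &= zmap.mask
    X = X4.reshape(n, -1)[:, mask.reshape(-1)]
    rng = np.random.default_rng(seed)
    null_max = _max_null_cluster_sizes(
        X, mask.reshape(-1), grid, t_cdt, n_perm, structure, rng
    )

    rows = []
    for cid, sign, size, peak_z, peak in records:
        p = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        rows.append(
            {
                "cluster_id": cid,
                "sign": sign,
                "size": size,
                "peak_z": peak_z,
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "p_fwe": p,
                "significant": p < alpha,
            }
        )
    table = pd.DataFrame(rows, columns=columns)
    return ClusterTable(table=table, labels=labels, cdt=cdt, alpha=alpha, n_perm=n_perm)


def extract_roi_means(cmap: ConnectivityMap, clusters: ClusterTable, significant_only: bool = True) -> np.ndarray:
    """Unweighted mean of a map over each cluster's voxels (one value per cluster)."""
    if clusters.labels.shape != cmap.grid:
        from .exceptions import GridMismatchError

        raise GridMismatchError("cluster label volume grid does not match map grid")
    tab = clusters.table
    if significant_only:
        tab = tab[tab["significant"]]
    out = []
    for cid in tab["cluster_id"]:
        voxels = clusters.labels == cid
        out.append(float(cmap.data[voxels].mean()))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA and BH FDR
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA with paired-t follow-ups."""

    F: float
    df_num: int
    df_den: int
    p: float
    pairwise: pd.DataFrame  # pair, t, df, p, p_fdr
    p_fdr: Optional[float] = None  # set when adjusted across an ROI family
    roi: Optional[int] = None


def repeated_measures_anova(
    roi_values: np.ndarray,
    condition_names: Optional[Sequence[str]] = None,
) -> RmAnovaResult:
    """Classical subjects-by-conditions decomposition (subject as blocking factor).

    ``roi_values`` is participants x conditions with complete cases.  F is
    MS(condition) / MS(subject x condition); follow-ups are two-sided paired
    t-tests for every condition pair.
    """
    Y = np.asarray(roi_values, dtype=float)
    if Y.ndim != 2:
        raise ValidationError("roi_values must be a participants x conditions matrix")
    n_sub, n_cond = Y.shape
    if n_cond < 2 or n_sub < 3:
        raise ValidationError("need >= 2 conditions and >= 3 participants")
    if not np.all(np.isfinite(Y)):
        raise ValidationError("roi_values contains missing cells; listwise-complete data required")
    names = list(condition_names) if condition_names is not None else [f"c{j}" for j in range(n_cond)]

    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_cond = float(n_sub * np.sum((cond_means - grand) ** 2))
    ss_subj = float(n_cond * np.sum((subj_means - grand) ** 2))
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_num = n_cond - 1
    df_den = (n_sub - 1) * (n_cond - 1)
    tiny = 1e-12 * max(ss_total, np.finfo(float).tiny)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ss_cond <= tiny:
        F, p = 0.0, 1.0
    elif ss_err <= tiny:
        F, p = np.inf, 0.0
    else:
        F = ms_cond / ms_err
        p = float(stats.f.sf(F, df_num, df_den))

    rows = []
    for a in range(n_cond):
        for b in range(a + 1, n_cond):
            d = Y[:, a] - Y[:, b]
            if np.allclose(d.std(ddof=1), 0.0):
                t_stat, pv = (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
            else:
                t_stat, pv = stats.ttest_rel(Y[:, a], Y[:, b])
            rows.append(
                {"pair": f"{names[a]} vs {names[b]}", "t": float(t_stat), "df": n_sub - 1, "p": float(pv)}
            )
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_fdr"] = fdr_bh(pairwise["p"].to_numpy())[0]
    else:
        pairwise["p_fdr"] = []
    return RmAnovaResult(F=float(F), df_num=df_num, df_den=df_den, p=float(p), pairwise=pairwise)


def roi_anova_family(
    roi_matrices: Sequence[np.ndarray],
    condition_names: Optional[Sequence[str]] = None,
) -> List[RmAnovaResult]:
    """Run the per-ROI ANOVAs and BH-FDR adjust across the ROI family."""
    results = [repeated_measures_anova(m, condition_names) for m in roi_matrices]
    if results:
        adj = fdr_bh(np.array([r.p for r in results]))[0]
        for i, r in enumerate(results):
            r.p_fdr = float(adj[i])
            r.roi = i + 1
    return results


def fdr_bh(pvalues: np.ndarray, q: float = 0.05):
    """Benjamini–Hochberg step-up FDR: adjusted p-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
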