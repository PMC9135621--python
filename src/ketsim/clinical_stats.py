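"""Group and symptom statistics on similarity coefficients.

Group comparisons follow the ANOVA conventions of multi-site clinical
imaging studies: the Fisher-z similarity coefficient is modelled on group,
sex, a group x sex interaction, and (when available) study site.  A
non-significant interaction is dropped and effects are reported from the
main-effects model, whose residual df then matches the shared-df style of
the reported contrasts (e.g. n = 361 with 7 sites gives t with 352 df;
n = 204 with three groups and sex gives 200 denominator df).  Effect sizes
are covariate-adjusted Cohen's d: adjusted mean difference divided by the
model residual SD, which reduces to classical pooled-SD d when no
covariates are present.  Within-group tests compare each group's estimated
marginal mean against zero using the model residual variance and df.

Symptom scores are the item sum plus the global severity rating, restricted
to participants with at least a mild global rating (>= 2); domain-wide
square-root transformation fires when the sample skewness of included raw
scores exceeds a threshold (default 1.0).  Each symptom model starts with a
similarity x sex interaction, drops it when non-significant, and the family
of domain tests is BH-FDR adjusted (8 for SAPS/SANS, 4 for SOPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import EstimationError, UndefinedStatisticError, ValidationError
from .group_inference import fdr_bh

# ---------------------------------------------------------------------------
# Symptom scores
# ---------------------------------------------------------------------------


@dataclass
class SymptomScore:
    participant_id: str
    scale: str
    domain: str
    items: np.ndarray
    global_rating: int
    raw_score: float
    score: float
    included: bool
    transformed: bool


def compute_symptom_score(
    items: Sequence[int],
    global_rating: int,
    participant_id: str = "",
    scale: str = "",
    domain: str = "",
    transform: bool = False,
) -> SymptomScore:
    """Domain score = sum of items + global rating; included iff global >= 2."""
    items = np.asarray(items, dtype=float)
    if np.any(items < 0) or global_rating < 0:
        raise ValidationError("symptom ratings must be non-negative")
    if np.any(items != np.round(items)):
        raise ValidationError("symptom items must be integers")
    raw = float(items.sum() + global_rating)
    score = float(np.sqrt(raw)) if transform else raw
    return SymptomScore(
        participant_id=participant_id,
        scale=scale,
        domain=domain,
        items=items.astype(int),
        global_rating=int(global_rating),
        raw_score=raw,
        score=score,
        included=global_rating >= 2,
        transformed=bool(transform),
    )


def score_symptom_table(symptoms: pd.DataFrame, skew_threshold: float = 1.0) -> pd.DataFrame:
    """Score every (scale, domain) of an item-level symptom table.

    The square-root transform is decided domain-wide from the sample
    skewness of included participants' raw scores, then applied to all of
    that domain's scores.
    """
    from .utils import sample_skewness

    item_cols = [c for c in symptoms.columns if c.startswith("item")]
    if not item_cols:
        raise ValidationError("symptom table has no item columns")
    out_rows = []
    for (scale, domain), sub in symptoms.groupby(["scale", "domain"], sort=False):
        items = sub[item_cols].to_numpy(dtype=float)
        if np.any(items < 0) or np.any(sub["global"].to_numpy() < 0):
            raise ValidationError(f"negative ratings in {scale}/{domain}")
        raw = items.sum(axis=1) + sub["global"].to_numpy(dtype=float)
        included = sub["global"].to_numpy() >= 2
        transform = False
        if included.sum() >= 3:
            transform = sample_skewness(raw[included]) > skew_threshold
        score = np.sqrt(raw) if transform else raw
        for i, (_, row) in enumerate(sub.iterrows()):
            out_rows.append(
                {
                    "id": row["id"],
                    "scale": scale,
                    "domain": domain,
                    "raw_score": float(raw[i]),
                    "score": float(score[i]),
                    "included": bool(included[i]),
                    "transformed": transform,
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Design-matrix helpers (explicit treatment/cell coding, no formula layer)
# ---------------------------------------------------------------------------


def _levels(series: pd.Series) -> List:
    return sorted(pd.unique(series))


def _dummy_block(series: pd.Series, levels: List) -> np.ndarray:
    """Treatment coding: indicator columns for every level after the first."""
    out = np.zeros((len(series), len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        out[:, j] = (series == lev).to_numpy(dtype=float)
    return out


class _GroupDesign:
    """Explicit design for fisher_z ~ group [* sex] [+ site]."""

    def __init__(self, df: pd.DataFrame, use_site: bool, interaction: bool):
        self.groups = _levels(df["group"])
        self.sexes = _levels(df["sex"])
        self.sites = _levels(df["site"]) if use_site else []
        self.use_site = use_site and len(self.sites) > 1
        self.interaction = interaction and len(self.sexes) > 1
        if len(self.groups) < 2:
            raise ValidationError("group_anova requires >= 2 groups")
        for g in self.groups:
            for s in self.sexes:
                if not len(df[(df["group"] == g) & (df["sex"] == s)]) and self.interaction:
                    raise EstimationError(f"empty design cell: group={g}, sex={s}")
        self.names: List[str] = ["intercept"]
        self.names += [f"group[{g}]" for g in self.groups[1:]]
        if len(self.sexes) > 1:
            self.names += [f"sex[{s}]" for s in self.sexes[1:]]
        if self.use_site:
            self.names += [f"site[{s}]" for s in self.sites[1:]]
        if self.interaction:
            self.names += [
                f"group[{g}]:sex[{s}]" for g in self.groups[1:] for s in self.sexes[1:]
            ]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        gblock = _dummy_block(df["group"], self.groups)
        cols.append(gblock)
        sblock = None
        if len(self.sexes) > 1:
            sblock = _dummy_block(df["sex"], self.sexes)
            cols.append(sblock)
        if self.use_site:
            cols.append(_dummy_block(df["site"], self.sites))
        if self.interaction:
            inter = np.einsum("ni,nj->nij", gblock, sblock).reshape(n, -1)
            cols.append(inter)
        return np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])

    def emmean_row(self, group) -> np.ndarray:
        """Prediction row for one group, averaged equally over sex and site."""
        row = np.zeros(len(self.names))
        row[0] = 1.0
        gi = {g: j for j, g in enumerate(self.groups[1:])}
        if group in gi:
            row[1 + gi[group]] = 1.0
        pos = 1 + len(self.groups) - 1
        if len(self.sexes) > 1:
            for j in range(len(self.sexes) - 1):
                row[pos + j] = 1.0 / len(self.sexes)
            pos += len(self.sexes) - 1
        if self.use_site:
            for j in range(len(self.sites) - 1):
                row[pos + j] = 1.0 / len(self.sites)
            pos += len(self.sites) - 1
        if self.interaction:
            for jg, g in enumerate(self.groups[1:]):
                for js in range(len(self.sexes) - 1):
                    if g == group:
                        row[pos + jg * (len(self.sexes) - 1) + js] = 1.0 / len(self.sexes)
        return row

    def slice_for(self, prefix: str) -> List[int]:
        return [j for j, nm in enumerate(self.names) if nm.startswith(prefix)]


# ---------------------------------------------------------------------------
# Group ANOVA
# ---------------------------------------------------------------------------


@dataclass
class GroupModelResult:
    omnibus_F: float
    omnibus_df: tuple
    omnibus_p: float
    contrasts: pd.DataFrame       # pair, estimate, t, df, p, p_fdr, d
    within_group: pd.DataFrame    # group, emmean, se, t, df, p
    interaction_p: float
    interaction_retained: bool
    residual_df: int
    residual_sd: float
    n: int
    family: Dict[str, object] = field(default_factory=dict)


def cohens_d(adjusted_diff: float, residual_sd: float) -> float:
    """Covariate-adjusted Cohen's d = adjusted mean difference / residual SD."""
    if residual_sd <= 0:
        raise UndefinedStatisticError("Cohen's d undefined for zero residual SD")
    return float(adjusted_diff / residual_sd)


def _fit_ols(y: np.ndarray, X: np.ndarray, names: List[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(f"singular design matrix (columns: {names})")
    return sm.OLS(y, X).fit()


def group_anova(
    sim: pd.DataFrame,
    use_site: bool = True,
    alpha_drop: float = 0.05,
) -> GroupModelResult:
    """ANOVA of Fisher-z similarity coefficients on group, sex (and site).

    Fits the group x sex interaction model first; if the interaction is not
    significant at ``alpha_drop`` it is dropped and all reported effects
    come from the main-effects model.  Reports the group omnibus F, pairwise
    group contrasts of estimated marginal means (BH-FDR adjusted, with
    covariate-adjusted Cohen's d), and within-group tests of each marginal
    mean against zero.
    """
    required = {"group", "sex", "fisher_z"} | ({"site"} if use_site else set())
    missing = required - set(sim.columns)
    if missing:
        raise ValidationError(f"similarity table missing columns: {sorted(missing)}")
    df = sim.reset_index(drop=True)
    y = df["fisher_z"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite similarity coefficients")

    full = _GroupDesign(df, use_site, interaction=True)
    interaction_p = np.nan
    if full.interaction:
        res_full = _fit_ols(y, full.matrix(df), full.names)
        idx = full.slice_for("group[")
        idx = [j for j in idx if ":" in full.names[j]]
        R = np.zeros((len(idx), len(full.names)))
        for r, j in enumerate(idx):
            R[r, j] = 1.0
        ftest = res_full.f_test(R)
        interaction_p = float(ftest.pvalue)
    retained = full.interaction and interaction_p < alpha_drop

    design = full if retained else _GroupDesign(df, use_site, interaction=False)
    res = _fit_ols(y, design.matrix(df), design.names)
    df_resid = int(res.df_resid)
    resid_sd = float(np.sqrt(res.mse_resid))
    cov = res.cov_params()
    params = res.params

    # Group omnibus F: joint test on group main-effect columns.
    gidx = [j for j in design.slice_for("group[") if ":" not in design.names[j]]
    R = np.zeros((len(gidx), len(design.names)))
    for r, j in enumerate(gidx):
        R[r, j] = 1.0
    ftest = res.f_test(R)
    omnibus_F = float(ftest.fvalue)
    omnibus_p = float(ftest.pvalue)
    omnibus_df = (len(gidx), df_resid)

    emm_rows = {g: design.emmean_row(g) for g in design.groups}
    within = []
    for g in design.groups:
        L = emm_rows[g]
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        p = 2 * float(stats.t.sf(abs(t), df_resid))
        within.append({"group": g, "emmean": est, "se": se, "t": t, "df": df_resid, "p": p})
    within = pd.DataFrame(within)

    pairs = []
    for i, g1 in enumerate(design.groups):
        for g2 in design.groups[i + 1 :]:
            L = emm_rows[g2] - emm_rows[g1]
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else np.nan
            p = 2 * float(stats.t.sf(abs(t), df_resid))
            pairs.append(
                {
                    "pair": f"{g2} vs {g1}",
                    "estimate": est,
                    "t": t,
                    "df": df_resid,
                    "p": p,
                    "d": cohens_d(est, resid_sd),
                }
            )
    contrasts = pd.DataFrame(pairs)
    contrasts["p_fdr"] = fdr_bh(contrasts["p"].to_numpy())[0]
    contrasts = contrasts[["pair", "estimate", "t", "df", "p", "p_fdr", "d"]]

    return GroupModelResult(
        omnibus_F=omnibus_F,
        omnibus_df=omnibus_df,
        omnibus_p=omnibus_p,
        contrasts=contrasts,
        within_group=within,
        interaction_p=interaction_p,
        interaction_retained=bool(retained),
        residual_df=df_resid,
        residual_sd=resid_sd,
        n=len(df),
        family={"name": "pairwise-group", "size": len(pairs)},
    )


# ---------------------------------------------------------------------------
# Symptom regressions
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    if s == 0:
        raise UndefinedStatisticError("cannot standardise a constant variable")
    return (x - x.mean()) / s


def _regression_design(df: pd.DataFrame, use_site: bool, with_interaction: bool):
    sexes = _levels(df["sex"])
    sites = _levels(df["site"]) if use_site and "site" in df.columns else []
    x = df["_x"].to_numpy()
    cols = [np.ones(len(df)), x]
    names = ["intercept", "similarity"]
    if len(sexes) > 1:
        sblock = _dummy_block(df["sex"], sexes)
        cols.append(sblock)
        names += [f"sex[{s}]" for s in sexes[1:]]
    if len(sites) > 1:
        cols.append(_dummy_block(df["site"], sites))
        names += [f"site[{s}]" for s in sites[1:]]
    if with_interaction and len(sexes) > 1:
        sblock = _dummy_block(df["sex"], sexes)
        cols.append(x[:, None] * sblock)
        names += [f"similarity:sex[{s}]" for s in sexes[1:]]
    X = np.column_stack([c if c.ndim == 2 else np.asarray(c)[:, None] for c in cols])
    return X, names, sexes


def symptom_regression(
    scores: pd.DataFrame,
    sim: pd.DataFrame,
    use_site: bool = True,
    alpha_drop: float = 0.05,
    min_n: int = 10,
) -> pd.DataFrame:
    """Regress each symptom domain's score on the similarity coefficient.

    ``scores`` is the output of :func:`score_symptom_table`; ``sim`` must
    carry id, fisher_z, sex (and site when ``use_site``).  Outcome and
    predictor are standardised within the included subsample, so the
    reported slope is a standardised beta (a raw slope in score units per
    Fisher-z unit is reported alongside).  Models start with the
    similarity x sex interaction; a non-significant interaction is dropped
    and the common slope is reported, otherwise per-sex slopes are fitted.
    BH FDR runs across the domain family of each scale group (SAPS/SANS
    together, SOPS alone).
    """
    rows = []
    for (scale, domain), sub in scores.groupby(["scale", "domain"], sort=False):
        inc = sub[sub["included"]]
        merged = inc.merge(sim, on="id", how="inner")
        row = {
            "scale": scale,
            "domain": domain,
            "n": len(merged),
            "slope_std": np.nan,
            "slope_raw": np.nan,
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "interaction_p": np.nan,
            "interaction_retained": False,
            "slope_std_M": np.nan,
            "slope_std_F": np.nan,
            "transformed": bool(sub["transformed"].iloc[0]) if len(sub) else False,
        }
        if len(merged) < min_n:
            rows.append(row)
            continue
        y_raw = merged["score"].to_numpy(dtype=float)
        x_raw = merged["fisher_z"].to_numpy(dtype=float)
        try:
            y = _standardize(y_raw)
            x = _standardize(x_raw)
        except UndefinedStatisticError:
            rows.append(row)
            continue
        d = merged.copy()
        d["_x"] = x
        one_sex = d["sex"].nunique() < 2
        interaction_p = np.nan
        if not one_sex:
            X, names, _ = _regression_design(d, use_site, with_interaction=True)
            try:
                res_int = _fit_ols(y, X, names)
                j = names.index([n for n in names if n.startswith("similarity:sex")][0])
                if res_int.mse_resid < 1e-10 * max(np.var(y), 1e-30):
                    # (near-)perfect fit: the t-test is numerical noise, so
                    # judge the interaction by its coefficient magnitude
                    interaction_p = 0.0 if abs(res_int.params[j]) > 1e-8 else 1.0
                else:
                    tval = res_int.tvalues[j]
                    interaction_p = 2 * float(stats.t.sf(abs(tval), res_int.df_resid))
            except EstimationError:
                interaction_p = np.nan
        retained = (not one_sex) and np.isfinite(interaction_p) and interaction_p < alpha_drop
        row["interaction_p"] = interaction_p
        row["interaction_retained"] = bool(retained)
        if retained:
            for sex in ("M", "F"):
                dsex = d[d["sex"] == sex]
                if len(dsex) < 3:
                    continue
                Xs, names_s, _ = _regression_design(dsex, use_site, with_interaction=False)
                ys = y[(d["sex"] == sex).to_numpy()]
                try:
                    res_s = _fit_ols(ys, Xs, names_s)
                    row[f"slope_std_{sex}"] = float(res_s.params[1])
                except EstimationError:
                    pass
            row["p"] = interaction_p
            row["df"] = res_int.df_resid
        else:
            X, names, _ = _regression_design(d, use_site, with_interaction=False)
            res = _fit_ols(y, X, names)
            slope = float(res.params[1])
            t = float(res.tvalues[1])
            p = 2 * float(stats.t.sf(abs(t), res.df_resid))
            row.update(
                {
                    "slope_std": slope,
                    "slope_raw": slope * y_raw.std(ddof=1) / x_raw.std(ddof=1),
                    "t": t,
                    "df": int(res.df_resid),
                    "p": p,
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)

    # FDR within scale families: SAPS+SANS form one 8-test family, SOPS its own.
    out["p_fdr"] = np.nan
    out["family"] = np.where(out["scale"].isin(["SAPS", "SANS"]), "SAPS/SANS", out["scale"])
    for fam, idx in out.groupby("family").groups.items():
        ps = out.loc[idx, "p"].to_numpy(dtype=float)
        ok = np.isfinite(ps)
        if ok.any():
            adj = np.full(ps.shape, np.nan)
            adj[ok] = fdr_bh(ps[ok])[0]
            out.loc[idx, "p_fdr"] = adj
    out["family_size"] = out.groupby("family")["family"].transform("size")
    return out


def spearman_confound(cpzeq: Sequence[float], fisher_z: Sequence[float]):
    """Spearman rank correlation (midrank ties) between dose and similarity."""
    x = np.asarray(cpzeq, dtype=float)
    y = np.asarray(fisher_z, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("spearman_confound requires paired vectors with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
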