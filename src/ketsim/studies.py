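"""Replicate studies: calibration, error control, and parameter recovery.

These functions run the pipeline's core stages over many independently
seeded synthetic replicates and summarise the outcome.  They are the
package's own evidence that the machinery behaves: normative z-scores are
calibrated on held-out controls, the cluster test controls its family-wise
error on null data, planted group loadings are recovered in the similarity
coefficients, and a planted symptom slope is recovered by the regression
stage.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clinical_stats import score_symptom_table, symptom_regression
from .config import SimConfig
from .group_inference import cluster_threshold, one_sample_t_map, z_map_from_t
from .maps import TemplateMap
from .normative import fit_normative_model, zscore_cohort
from .similarity import similarity_table
from .synthetic import (
    make_cohort_fields,
    make_template_pattern,
    simulate_between_day_contrasts,
    simulate_cohort,
    simulate_connectivity_map,
    simulate_symptom_table,
)
from .utils import substream


def _replicate_seed(root_seed: int, label: str, rep: int) -> int:
    """A fresh sub-2^31 seed per replicate, derived from the root seed."""
    rng = substream(root_seed, label, rep)
    return int(rng.integers(0, 2**31 - 1))


def normative_calibration(
    config: Optional[SimConfig] = None,
    n_fit: int = 200,
    n_holdout: int = 200,
    seed: int = 20220414,
) -> Dict[str, float]:
    """Held-out HC calibration of the normative site model.

    Fits the per-voxel site regression on ``n_fit`` HC and scores ``n_holdout``
    fresh HC drawn from the same generative population.  Well-calibrated
    deviation scores have pooled mean ~0 and pooled SD ~1 across held-out
    participants and voxels.
    """
    base = config or SimConfig()
    cfg = dataclasses.replace(
        base,
        n_participants_per_group={"HC": n_fit + n_holdout},
        rng_seed=_replicate_seed(seed, "calibration", 0),
    )
    cohort = simulate_cohort(cfg)
    template = make_template_pattern(cfg)
    fields = make_cohort_fields(cfg)
    maps = [simulate_connectivity_map(p, template, cfg, fields) for p in cohort]
    pheno = cohort.to_frame()

    fit_maps, fit_cov = maps[:n_fit], pheno.iloc[:n_fit].reset_index(drop=True)
    hold_maps, hold_cov = maps[n_fit:], pheno.iloc[n_fit:].reset_index(drop=True)
    model = fit_normative_model(fit_maps, fit_cov, kind="site")
    zmaps = zscore_cohort(hold_maps, hold_cov, model)
    Z = np.stack([zm.data[model.mask] for zm in zmaps])
    return {
        "mean": float(Z.mean()),
        "sd": float(Z.std(ddof=1)),
        "n_holdout": n_holdout,
        "n_fit": n_fit,
        "n_voxels": int(model.mask.sum()),
    }


def null_cluster_fwe_rate(
    config: Optional[SimConfig] = None,
    n_reps: int = 200,
    n_participants: int = 18,
    n_perm: int = 500,
    cdt: float = 3.29,
    alpha: float = 0.05,
    seed: int = 20220414,
) -> Dict[str, float]:
    """Observed family-wise error of the cluster test on null replicates.

    Each replicate draws ``n_participants`` zero-effect between-day contrast
    maps, runs the group one-sample test and the sign-flipping cluster
    correction, and records whether any cluster survives.  The returned
    rate estimates the test's family-wise error, nominally ``alpha``.
    """
    base = config or SimConfig()
    hits = 0
    for rep in range(n_reps):
        rep_seed = _replicate_seed(seed, "null-cluster", rep)
        cfg = dataclasses.replace(base, rng_seed=rep_seed)
        maps = simulate_between_day_contrasts(n_participants, cfg, delta=0.0)
        tmap = one_sample_t_map(maps)
        zmap = z_map_from_t(tmap)
        table = cluster_threshold(
            zmap, maps, cdt=cdt, alpha=alpha, n_perm=n_perm, seed=rep_seed
        )
        if table.n_significant > 0:
            hits += 1
    return {
        "rate": hits / n_reps,
        "n_reps": n_reps,
        "n_participants": n_participants,
        "n_perm": n_perm,
        "alpha": alpha,
    }


def _clinical_replicate(cfg: SimConfig):
    """One clinical-arm replicate: maps -> normative z -> similarity table."""
    cohort = simulate_cohort(cfg)
    template = make_template_pattern(cfg)
    fields = make_cohort_fields(cfg)
    maps = [simulate_connectivity_map(p, template, cfg, fields) for p in cohort]
    pheno = cohort.to_frame()
    hc = pheno.index[pheno["group"] == "HC"].tolist()
    model = fit_normative_model([maps[i] for i in hc], pheno.iloc[hc].reset_index(drop=True), "site")
    zmaps = zscore_cohort(maps, pheno, model)
    tab = similarity_table(zmaps, TemplateMap(data=template.data, provenance="synthetic-truth"))
    return cohort, tab.merge(pheno, on="id")


def loading_order_recovery(
    config: Optional[SimConfig] = None,
    n_reps: int = 100,
    seed: int = 20220414,
) -> Dict[str, float]:
    """How often the planted loading order appears in group mean Fisher-z.

    With the default loadings (HC 0 < CHR-P 0.15 < ESZ 0.3) the group means
    of the Fisher-z similarity coefficients should be strictly ordered
    HC < CHR-P < ESZ in nearly every replicate.
    """
    base = config or SimConfig()
    order = sorted(base.n_participants_per_group, key=lambda g: base.template_loading.get(g, 0.0))
    correct = 0
    means = []
    for rep in range(n_reps):
        cfg = dataclasses.replace(base, rng_seed=_replicate_seed(seed, "ordering", rep))
        _, tab = _clinical_replicate(cfg)
        m = tab.groupby("group")["fisher_z"].mean()
        means.append(m)
        vals = [m[g] for g in order]
        if all(a < b for a, b in zip(vals, vals[1:])):
            correct += 1
    mean_by_group = pd.concat(means, axis=1).mean(axis=1)
    out = {"fraction_correct": correct / n_reps, "n_reps": n_reps}
    out.update({f"mean_fisher_z_{g}": float(mean_by_group[g]) for g in order})
    return out


def symptom_slope_recovery(
    config: Optional[SimConfig] = None,
    n_reps: int = 50,
    seed: int = 20220414,
) -> Dict[str, float]:
    """Recovery of the planted hallucination-score slope.

    Symptoms are generated from each participant's measured Fisher-z
    similarity with the configured slope; the regression stage should
    recover that slope (in score units per Fisher-z unit) within Monte-Carlo
    error across replicates.
    """
    base = config or SimConfig()
    planted = float(base.symptom_slopes.get("Hallucinations", base.symptom_slope))
    estimates = []
    std_estimates = []
    for rep in range(n_reps):
        cfg = dataclasses.replace(base, rng_seed=_replicate_seed(seed, "symptom", rep))
        cohort, tab = _clinical_replicate(cfg)
        fz = dict(zip(tab["id"], tab["fisher_z"]))
        symptoms = simulate_symptom_table(cohort, fz, cfg)
        scored = score_symptom_table(symptoms)
        res = symptom_regression(scored, tab, use_site=True)
        row = res[res["domain"] == "Hallucinations"]
        if len(row) and np.isfinite(row["slope_raw"].iloc[0]):
            estimates.append(float(row["slope_raw"].iloc[0]))
            std_estimates.append(float(row["slope_std"].iloc[0]))
    estimates = np.asarray(estimates)
    mc_se = float(estimates.std(ddof=1) / np.sqrt(len(estimates)))
    return {
        "planted_slope": planted,
        "mean_estimate": float(estimates.mean()),
        "mc_se": mc_se,
        "mean_std_beta": float(np.mean(std_estimates)),
        "n_reps": int(len(estimates)),
    }
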