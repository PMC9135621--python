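"""End-to-end orchestration of the simulated study.

``run_pipeline`` executes the stages in dependency order:

1. drug arm — simulate two-phase drug sessions for healthy volunteers,
   fit first-level seed GLMs per run, and build within-day and between-day
   fixed-effects contrasts;
2. group inference — one-sample t over between-day contrasts, z-transform
   (this unthresholded z-map is the dysconnectivity template), cluster-extent
   permutation inference, ROI extraction and the three-condition
   repeated-measures ANOVA family;
3. clinical arm — simulate the clinical cohorts' connectivity maps, fit the
   HC normative site model, score deviation z-maps, compute template
   similarity coefficients;
4. statistics — group ANOVA on Fisher-z similarity, symptom regressions
   with the interaction-dropping procedure, and the antipsychotic-dose
   (CPZeq) Spearman confound check.

Every written output carries a JSON sidecar with the configuration hash and
seed; the run manifest lists each file with a SHA-256 digest, so two runs of
the same configuration can be compared byte-for-byte.  No timestamps are
recorded — a run is a pure function of its configuration.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .clinical_stats import (
    group_anova,
    score_symptom_table,
    spearman_confound,
    symptom_regression,
)
from .config import DAYS, RunConfig
from .contrasts import session_contrasts
from .exceptions import ValidationError
from .group_inference import (
    cluster_threshold,
    extract_roi_means,
    one_sample_t_map,
    roi_anova_family,
    z_map_from_t,
)
from .io import write_json, write_map, write_sidecar, write_table
from .maps import TemplateMap
from .normative import fit_normative_model, zscore_cohort
from .seed_connectivity import run_to_beta_map, threshold_seed
from .similarity import similarity_table
from .synthetic import (
    make_seed_probability_map,
    make_template_pattern,
    simulate_cohort,
    simulate_connectivity_cohort,
    simulate_drug_study,
    simulate_symptom_table,
)
from .utils import substream


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage; returns the manifest (also written to the run dir)."""
    sim = config.sim
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = sim.rng_seed
    outputs: List[Path] = []
    log: List[str] = []

    def emit_map(name, data, stage, extra=None):
        p = write_map(outdir / name, data)
        write_sidecar(p, stage, chash, seed, extra)
        outputs.append(p)
        return p

    def emit_table(name, table, stage, extra=None):
        p = write_table(outdir / name, table)
        write_sidecar(p, stage, chash, seed, extra)
        outputs.append(p)
        return p

    # ------------------------------------------------------------------ drug arm
    seed_prob = make_seed_probability_map(sim)
    seed_def = threshold_seed(seed_prob, config.seed_threshold)
    log.append(f"seed mask: {seed_def.n_voxels} voxels at threshold {config.seed_threshold}")
    emit_map("seed_probability.nii.gz", seed_prob, "simulate")

    between: List = []
    drug_avgs: Dict[str, List] = {day: [] for day in DAYS}
    ket_ids: List[str] = []
    current_id = None
    maps_by_day: Dict[str, List] = {}
    for participant, day, runs in simulate_drug_study(sim):
        if participant.id != current_id:
            if current_id is not None:
                contrasts = session_contrasts(maps_by_day, sim.runs_per_condition)
                between.append(contrasts["between"])
                for d in DAYS:
                    drug_avgs[d].append(contrasts[f"{d}:drug"])
            current_id = participant.id
            ket_ids.append(participant.id)
            maps_by_day = {}
        maps_by_day[day] = [run_to_beta_map(r, seed_def) for r in runs]
    if current_id is not None:
        contrasts = session_contrasts(maps_by_day, sim.runs_per_condition)
        between.append(contrasts["between"])
        for d in DAYS:
            drug_avgs[d].append(contrasts[f"{d}:drug"])
    if len(between) < 2:
        raise ValidationError("drug arm needs at least 2 participants (n_ketamine)")
    for cmap in between:
        emit_map(f"contrast_between_{cmap.participant_id}.nii.gz", cmap.data, "contrast")

    # --------------------------------------------------------------- group map
    tmap = one_sample_t_map(between)
    zmap = z_map_from_t(tmap)
    emit_map("template_zmap.nii.gz", zmap.data, "group-map", {"n": tmap.n, "df": tmap.df})
    template = TemplateMap(data=zmap.data, provenance=f"group z-map (n={tmap.n})")

    clusters = cluster_threshold(
        zmap,
        between,
        cdt=config.cdt,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seed,
    )
    emit_table(
        "clusters.tsv",
        clusters.table,
        "cluster",
        {"cdt": config.cdt, "alpha": config.alpha, "n_perm": config.n_perm},
    )
    emit_map("cluster_labels.nii.gz", clusters.labels.astype(float), "cluster")
    log.append(f"clusters: {len(clusters.table)} candidates, {clusters.n_significant} significant")

    # --------------------------------------------------------------- ROI ANOVA
    roi_rows = []
    n_sig = clusters.n_significant
    if n_sig:
        condition_names = ["placebo_ketamine", "active_ketamine", "lamotrigine_ketamine"]
        day_order = ["PL-PK", "PL-AK", "AL-AK"]
        matrices = []
        for roi_index in range(n_sig):
            mat = np.zeros((len(ket_ids), 3))
            for c, day in enumerate(day_order):
                for r, cmap in enumerate(drug_avgs[day]):
                    mat[r, c] = extract_roi_means(cmap, clusters)[roi_index]
            matrices.append(mat)
        results = roi_anova_family(matrices, condition_names)
        for res in results:
            for _, prow in res.pairwise.iterrows():
                roi_rows.append(
                    {
                        "roi": res.roi,
                        "F": res.F,
                        "df_num": res.df_num,
                        "df_den": res.df_den,
                        "anova_p": res.p,
                        "anova_p_fdr": res.p_fdr,
                        "pair": prow["pair"],
                        "pair_t": prow["t"],
                        "pair_p": prow["p"],
                        "pair_p_fdr": prow["p_fdr"],
                    }
                )
        log.append(f"ROI ANOVA family size: {len(results)}")
    emit_table(
        "roi_anova.tsv",
        pd.DataFrame(
            roi_rows,
            columns=[
                "roi", "F", "df_num", "df_den", "anova_p", "anova_p_fdr",
                "pair", "pair_t", "pair_p", "pair_p_fdr",
            ],
        ),
        "roi-anova",
        {"family_size": n_sig},
    )

    # ------------------------------------------------------------ clinical arm
    cohort = simulate_cohort(sim)
    pheno = cohort.to_frame()
    emit_table("phenotypes.tsv", pheno.drop(columns=["true_loading"]), "simulate")
    truth = make_template_pattern(sim)
    cmaps = simulate_connectivity_cohort(cohort, truth, sim)

    hc_idx = pheno.index[pheno["group"] == "HC"].tolist()
    model = fit_normative_model(
        [cmaps[i] for i in hc_idx], pheno.iloc[hc_idx].reset_index(drop=True), kind="site"
    )
    dropped = int((~model.mask).sum())
    log.append(f"normative site model: n_hc={model.n_hc}, masked voxels dropped: {dropped}")
    zmaps = zscore_cohort(cmaps, pheno, model)
    sim_tab = similarity_table(zmaps, template)
    sim_tab = sim_tab.merge(pheno[["id", "group", "site", "age", "sex"]], on="id")
    emit_table("similarity.tsv", sim_tab, "similarity", {"n_voxels": int(sim_tab["n_voxels"].iloc[0])})

    # ------------------------------------------------------------------ stats
    gres = group_anova(sim_tab, use_site=True, alpha_drop=config.alpha_drop)
    emit_table("group_contrasts.tsv", gres.contrasts, "stats")
    emit_table("group_within.tsv", gres.within_group, "stats")
    group_summary = pd.DataFrame(
        [
            {
                "F": gres.omnibus_F,
                "df_num": gres.omnibus_df[0],
                "df_den": gres.omnibus_df[1],
                "p": gres.omnibus_p,
                "interaction_p": gres.interaction_p,
                "interaction_retained": gres.interaction_retained,
                "residual_sd": gres.residual_sd,
                "n": gres.n,
            }
        ]
    )
    emit_table("group_anova.tsv", group_summary, "stats")

    fz_by_id = dict(zip(sim_tab["id"], sim_tab["fisher_z"]))
    symptoms = simulate_symptom_table(cohort, fz_by_id, sim)
    sym_rows = pd.DataFrame()
    if len(symptoms):
        emit_table("symptom_items.tsv", symptoms, "simulate")
        scored = score_symptom_table(symptoms, config.skew_threshold)
        sym_rows = symptom_regression(
            scored, sim_tab, use_site=True, alpha_drop=config.alpha_drop
        )
        emit_table("symptom_regressions.tsv", sym_rows, "stats")

    # CPZeq confound: dose is an input column in real analyses; simulated as
    # a loading-independent log-normal for medicated groups here.
    confound = {}
    med = pheno[pheno["group"].isin(["SZ", "ESZ"])]
    if len(med) >= 5:
        rng = substream(seed, "cpzeq")
        cpz = np.round(np.exp(rng.normal(5.3, 0.8, size=len(med))), 1)
        fz = sim_tab.set_index("id").loc[med["id"], "fisher_z"].to_numpy()
        rho, p = spearman_confound(cpz, fz)
        confound = {"spearman_rho": rho, "p": p, "n": int(len(med))}
        emit_table(
            "cpzeq.tsv", pd.DataFrame({"id": med["id"].to_numpy(), "cpzeq_mg_day": cpz}), "simulate"
        )

    families = {
        "pairwise-group": gres.family["size"],
        "roi-anova": n_sig,
    }
    if len(sym_rows):
        for fam, size in sym_rows.groupby("family")["family_size"].first().items():
            families[fam] = int(size)

    manifest = {
        "version": __version__,
        "config_hash": chash,
        "rng_seed": seed,
        "thresholds": {
            "cdt": config.cdt,
            "alpha": config.alpha,
            "fdr_q": config.fdr_q,
            "seed_threshold": config.seed_threshold,
            "alpha_drop": config.alpha_drop,
            "skew_threshold": config.skew_threshold,
            "n_perm": config.n_perm,
        },
        "fdr_families": families,
        "confound": confound,
        "log": log,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
    }
    write_json(outdir / "manifest.json", manifest)
    return manifest
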