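"""Generator behaviour: determinism, planted structure, and null structure."""

import dataclasses

import numpy as np
import pytest

from ketsim.config import SimConfig
from ketsim.contrasts import session_contrasts
from ketsim.group_inference import cluster_threshold, one_sample_t_map, z_map_from_t
from ketsim.exceptions import ValidationError
from ketsim.seed_connectivity import run_to_beta_map, threshold_seed
from ketsim.synthetic import (
    make_seed_probability_map,
    make_template_pattern,
    simulate_bold_session,
    simulate_cohort,
    simulate_connectivity_cohort,
    simulate_symptoms,
    simulate_symptom_table,
)


def test_same_seed_reproduces_everything(small_config):
    c1 = simulate_cohort(small_config)
    c2 = simulate_cohort(small_config)
    assert c1.to_frame().equals(c2.to_frame())
    t = make_template_pattern(small_config)
    m1 = simulate_connectivity_cohort(c1, t, small_config)
    m2 = simulate_connectivity_cohort(c2, t, small_config)
    assert all(np.array_equal(a.data, b.data) for a, b in zip(m1, m2))
    p = c1.participants[0]
    r1 = simulate_bold_session(p, "active_ketamine", small_config)[0]
    r2 = simulate_bold_session(p, "active_ketamine", small_config)[0]
    assert np.array_equal(r1.data, r2.data)


def test_unknown_group_label_rejected(small_config):
    with pytest.raises(ValidationError):
        SimConfig(
            grid_dims=(12, 12, 12),
            n_participants_per_group={"XX": 5},
        )


def test_zero_loading_cohorts_center_on_zero():
    """With all planted loadings zero, group mean loadings are 0 within 3 SE."""
    means = {"HC": [], "SZ": []}
    for rep in range(200):
        cfg = SimConfig(
            grid_dims=(12, 12, 12),
            n_participants_per_group={"HC": 5, "SZ": 5},
            template_loading={"HC": 0.0, "SZ": 0.0},
            rng_seed=1000 + rep,
        )
        frame = simulate_cohort(cfg).to_frame()
        for g in means:
            means[g].append(frame.loc[frame["group"] == g, "true_loading"].mean())
    for g, vals in means.items():
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-12


def test_planted_group_gap_in_loadings_recovered():
    """lambda_SZ=0.5 vs lambda_HC=0 separates sample means in >=95% of replicates."""
    wins = 0
    for rep in range(100):
        cfg = SimConfig(
            grid_dims=(12, 12, 12),
            n_participants_per_group={"HC": 20, "SZ": 20},
            template_loading={"HC": 0.0, "SZ": 0.5},
            rng_seed=2000 + rep,
        )
        frame = simulate_cohort(cfg).to_frame()
        g = frame.groupby("group")["true_loading"].mean()
        wins += g["SZ"] > g["HC"]
    assert wins >= 95


def test_noiseless_seed_voxels_have_unit_beta(small_config):
    """With zero noise, seed voxels couple to the latent series with beta 1."""
    cfg = dataclasses.replace(small_config, bold_noise_sd=0.0)
    cohort = simulate_cohort(cfg)
    run = simulate_bold_session(cohort.participants[0], "placebo_ketamine", cfg, noise_sd=0.0)[0]
    seed = threshold_seed(make_seed_probability_map(cfg), 0.8)
    beta = run_to_beta_map(run, seed)
    assert np.allclose(beta.data[seed.binary_mask], 1.0, atol=1e-9)


def test_null_drug_effect_gives_zero_between_day_contrast(small_config):
    """No coupling difference between conditions -> between-day contrast is ~0."""
    cfg = dataclasses.replace(small_config, coupling_delta=0.0, bold_noise_sd=0.0)
    cohort = simulate_cohort(cfg)
    p = cohort.participants[0]
    seed = threshold_seed(make_seed_probability_map(cfg), 0.8)
    maps_by_day = {}
    for day, cond in (("PL-PK", "placebo_ketamine"), ("PL-AK", "active_ketamine")):
        runs = simulate_bold_session(p, cond, cfg, noise_sd=0.0)
        maps_by_day[day] = [run_to_beta_map(r, seed) for r in runs]
    out = session_contrasts(maps_by_day, cfg.runs_per_condition)
    assert np.allclose(out["between"].data, 0.0, atol=1e-9)


def test_planted_coupling_increase_recovered_by_cluster_inference():
    """End-to-end: the planted sensory hyper-coupling survives cluster correction."""
    cfg = SimConfig(
        grid_dims=(12, 12, 12),
        n_participants_per_group={"HC": 2},
        n_ketamine=8,
        n_timepoints_per_run=60,
        coupling_delta=0.5,
        bold_noise_sd=0.05,
        rng_seed=99,
    )
    seed = threshold_seed(make_seed_probability_map(cfg), 0.8)
    template = make_template_pattern(cfg)
    between = []
    from ketsim.synthetic import simulate_drug_study

    maps_by_day = {}
    current = None
    for participant, day, runs in simulate_drug_study(cfg, days=("PL-PK", "PL-AK")):
        if participant.id != current:
            if current is not None:
                between.append(session_contrasts(maps_by_day, cfg.runs_per_condition)["between"])
            current = participant.id
            maps_by_day = {}
        maps_by_day[day] = [run_to_beta_map(r, seed) for r in runs]
    between.append(session_contrasts(maps_by_day, cfg.runs_per_condition)["between"])

    zmap = z_map_from_t(one_sample_t_map(between))
    table = cluster_threshold(zmap, between, n_perm=200, seed=cfg.rng_seed)
    assert table.n_significant >= 1
    # the surviving cluster overlaps the planted sensory region
    sig = table.significant_labels() > 0
    assert (sig & (template.data > 0)).sum() > 0


def test_symptom_inclusion_fraction_matches_configured_subthreshold_rate():
    cfg = SimConfig(
        grid_dims=(12, 12, 12),
        n_participants_per_group={"ESZ": 300},
        subthreshold_global_fraction=0.3,
        rng_seed=5,
    )
    cohort = simulate_cohort(cfg)
    table = simulate_symptom_table(cohort, {p.id: 0.0 for p in cohort}, cfg)
    frac_included = (table["global"] >= 2).mean()
    assert abs(frac_included - 0.7) < 0.05


def test_symptom_noiseless_limit_is_perfectly_linear(small_config):
    """slope=2, noise->0: scores track Fisher-z almost exactly (rounding aside)."""
    cfg = dataclasses.replace(
        small_config,
        symptom_slopes={"Hallucinations": 20.0},
        symptom_noise_sd=1e-9,
        symptom_intercept=20.0,
        subthreshold_global_fraction=0.0,
    )
    cohort = simulate_cohort(cfg)
    esz = [p for p in cohort if p.group == "ESZ"]
    fz = np.linspace(-0.5, 0.5, len(esz))
    sums = []
    for p, z in zip(esz, fz):
        tab = simulate_symptoms(p, z, cfg)
        hall = tab[tab["domain"] == "Hallucinations"]
        sums.append(hall[[f"item{i+1}" for i in range(5)]].to_numpy().sum())
    r = np.corrcoef(fz, sums)[0, 1]
    assert r > 0.97
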