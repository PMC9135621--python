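"""Symptom scoring, group ANOVA machinery, and symptom regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ketsim.clinical_stats import (
    cohens_d,
    compute_symptom_score,
    group_anova,
    score_symptom_table,
    spearman_confound,
    symptom_regression,
)
from ketsim.exceptions import UndefinedStatisticError, ValidationError


def _sim_table(rng, sizes, means, sd=1.0, n_sites=3):
    rows = []
    i = 0
    for g, n in sizes.items():
        for j in range(n):
            rows.append(
                {
                    "id": f"s{i}",
                    "group": g,
                    "sex": "M" if j % 2 == 0 else "F",
                    "site": i % n_sites,
                    "fisher_z": means[g] + sd * rng.standard_normal(),
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestSymptomScore:
    def test_subthreshold_global_excluded(self):
        s = compute_symptom_score([4, 4, 4, 4], global_rating=1)
        assert not s.included

    def test_sum_rule(self):
        s = compute_symptom_score([2, 3, 0, 1], global_rating=3)
        assert s.raw_score == 9

    def test_sqrt_transform(self):
        s = compute_symptom_score([2, 3, 0, 1], global_rating=3, transform=True)
        assert s.score == pytest.approx(3.0)

    def test_negative_ratings_rejected(self):
        with pytest.raises(ValidationError):
            compute_symptom_score([1, -2], global_rating=3)

    def test_skew_rule_fires_domain_wide(self, rng):
        # heavily right-skewed raw scores trigger the domain-wide sqrt
        n = 60
        skewed = np.concatenate([np.ones(50), np.full(10, 20.0)]).astype(int)
        rows = []
        for i in range(n):
            rows.append(
                {"id": f"s{i}", "scale": "SAPS", "domain": "Hallucinations",
                 "item1": int(skewed[i]), "item2": 0, "item3": 0, "item4": 0, "item5": 0,
                 "global": 3}
            )
        scored = score_symptom_table(pd.DataFrame(rows))
        assert scored["transformed"].all()
        assert scored["score"].iloc[0] == pytest.approx(np.sqrt(skewed[0] + 3))


class TestGroupAnova:
    def test_null_groups_give_small_d_and_uniform_p(self, rng):
        ds, ps = [], []
        for _ in range(60):
            tab = _sim_table(rng, {"HC": 40, "SZ": 40}, {"HC": 0.0, "SZ": 0.0})
            res = group_anova(tab, use_site=True)
            ds.append(res.contrasts["d"].iloc[0])
            ps.append(res.omnibus_p)
        assert abs(np.mean(ds)) < 0.08
        assert 0.35 < np.mean(ps) < 0.65

    def test_planted_standardised_gap_recovered(self, rng):
        """A planted 0.8 SD group gap yields mean estimated d in (0.7, 0.9)."""
        ds = []
        for _ in range(100):
            tab = _sim_table(rng, {"HC": 180, "SZ": 180}, {"HC": 0.0, "SZ": 0.8})
            res = group_anova(tab, use_site=True)
            row = res.contrasts[res.contrasts["pair"].str.contains("SZ")]
            ds.append(row["d"].iloc[0])
        assert 0.7 < np.mean(ds) < 0.9

    def test_within_group_tests_use_model_df(self, rng):
        tab = _sim_table(rng, {"HC": 30, "SZ": 30}, {"HC": 0.0, "SZ": 0.5})
        res = group_anova(tab, use_site=True)
        assert (res.within_group["df"] == res.residual_df).all()
        assert res.contrasts["p_fdr"].iloc[0] >= res.contrasts["p"].iloc[0] - 1e-12

    def test_no_covariate_case_reduces_to_classical_pooled_d(self, rng):
        # single sex, no site: adjusted d must equal textbook pooled-SD d
        n = 25
        y1 = rng.standard_normal(n)
        y2 = rng.standard_normal(n) + 0.6
        tab = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(2 * n)],
                "group": ["HC"] * n + ["SZ"] * n,
                "sex": ["M"] * (2 * n),
                "site": [0] * (2 * n),
                "fisher_z": np.concatenate([y1, y2]),
            }
        )
        res = group_anova(tab, use_site=False)
        pooled = np.sqrt(((n - 1) * y1.var(ddof=1) + (n - 1) * y2.var(ddof=1)) / (2 * n - 2))
        classical = (y2.mean() - y1.mean()) / pooled
        assert res.contrasts["d"].iloc[0] == pytest.approx(classical, abs=1e-10)

    def test_empty_cell_named_in_error(self, rng):
        tab = _sim_table(rng, {"HC": 10, "SZ": 10}, {"HC": 0.0, "SZ": 0.0})
        tab.loc[tab["group"] == "SZ", "sex"] = "M"  # no SZ females
        tab.loc[tab["group"] == "HC", "sex"] = ["M", "F"] * 5
        from ketsim.exceptions import EstimationError

        with pytest.raises(EstimationError, match="SZ"):
            group_anova(tab, use_site=False)

    def test_cohens_d_definition(self):
        assert cohens_d(0.0, 1.0) == 0.0
        assert cohens_d(1.0, 1.0) == 1.0
        with pytest.raises(UndefinedStatisticError):
            cohens_d(1.0, 0.0)


def _scored(ids, scores):
    return pd.DataFrame(
        {
            "id": ids,
            "scale": "SAPS",
            "domain": "Hallucinations",
            "raw_score": scores,
            "score": scores,
            "included": True,
            "transformed": False,
        }
    )


class TestSymptomRegression:
    def test_perfectly_linear_scores_give_unit_standardised_slope(self, rng):
        tab = _sim_table(rng, {"SZ": 40}, {"SZ": 0.2}, sd=0.3)
        scored = _scored(tab["id"], tab["fisher_z"].to_numpy())
        res = symptom_regression(scored, tab, use_site=True)
        assert res["slope_std"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_null_slope_rejection_rate_is_nominal(self, rng):
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            tab = _sim_table(rng, {"SZ": 60}, {"SZ": 0.0}, sd=0.3)
            scored = _scored(tab["id"], rng.standard_normal(60))
            res = symptom_regression(scored, tab, use_site=True)
            if res["p"].iloc[0] < 0.05:
                hits += 1
        rate = hits / n_reps
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_null_interaction_dropped_at_nominal_rate(self, rng):
        retained = 0
        n_reps = 200
        for _ in range(n_reps):
            tab = _sim_table(rng, {"SZ": 60}, {"SZ": 0.0}, sd=0.3)
            scored = _scored(tab["id"], rng.standard_normal(60))
            res = symptom_regression(scored, tab, use_site=True)
            retained += bool(res["interaction_retained"].iloc[0])
        rate = retained / n_reps
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_slope_invariant_to_outcome_rescaling(self, rng):
        tab = _sim_table(rng, {"SZ": 50}, {"SZ": 0.1}, sd=0.3)
        base_scores = 3.0 * tab["fisher_z"].to_numpy() + rng.standard_normal(50)
        r1 = symptom_regression(_scored(tab["id"], base_scores), tab)
        r2 = symptom_regression(_scored(tab["id"], 10.0 * base_scores + 5.0), tab)
        assert r1["slope_std"].iloc[0] == pytest.approx(r2["slope_std"].iloc[0], abs=1e-10)

    def test_family_sizes_are_recorded(self, rng):
        frames = []
        for scale, domains in (
            ("SAPS", ["Hallucinations", "Delusions", "Thought Disorder", "Bizarre Behavior"]),
            ("SANS", ["Affective Flattening", "Alogia", "Avolition/Apathy", "Anhedonia/Asociality"]),
        ):
            for d in domains:
                f = _scored([f"s{i}" for i in range(40)], rng.standard_normal(40))
                f["scale"] = scale
                f["domain"] = d
                frames.append(f)
        scored = pd.concat(frames, ignore_index=True)
        tab = _sim_table(rng, {"SZ": 40}, {"SZ": 0.0}, sd=0.3)
        res = symptom_regression(scored, tab)
        assert (res["family_size"] == 8).all()
        assert (res["family"] == "SAPS/SANS").all()


class TestSpearman:
    def test_identity_gives_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, _ = spearman_confound(x, x)
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman_confound(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_tied_instance_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_confound(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_confound(np.ones(6), np.arange(6.0))
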