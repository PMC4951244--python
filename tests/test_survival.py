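"""Kaplan-Meier, log-rank, quartile stratification, Cox and paired tests."""

import numpy as np
import pandas as pd
import pytest

from mutanome import survival as surv
from mutanome.config import CohortConfig
from mutanome.synthetic import generate_outcomes


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = surv.km_estimate([1, 2, 3], [1, 1, 1]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_censoring_between_events(self):
        # events at 1 and 3, censored at 2: S = 3/4, then 3/4 * 1/2
        km = surv.km_estimate([1, 2, 3, 4], [1, 0, 1, 0]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(3 / 4)
        assert km.loc[3.0] == pytest.approx(3 / 8)

    def test_all_censored_flat(self):
        km = surv.km_estimate([5, 6, 7], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_subject_event(self):
        km = surv.km_estimate([5], [1]).set_index("time")["survival"]
        assert km.loc[0.0] == 1.0
        assert km.loc[5.0] == 0.0

    def test_monotone_non_increasing(self, cohort):
        clin = cohort.clinical
        km = surv.km_estimate(clin["time_months"], clin["event"])
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            surv.km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 0, 1]
        stat, p, dof = surv.logrank_test({"a": (t, e), "b": (t, e)})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_two_event_risk_table_by_hand(self):
        # A: events at 1 and 2; B: censored at 10, 10.
        # t=1: n=4, nA=2, d=1 -> E_A = 1/2, V = (2*2*1*3)/(16*3) = 1/4
        # t=2: n=3, nA=1, d=1 -> E_A = 1/3, V = (1*2*1*2)/(9*2) = 2/9
        # O-E = 2 - 5/6 = 7/6; chi2 = (7/6)^2 / (1/4 + 2/9) = 2.88235...
        stat, p, dof = surv.logrank_test(
            {"A": ([1, 2], [1, 1]), "B": ([10, 10], [0, 0])}
        )
        expected = (7 / 6) ** 2 / (1 / 4 + 2 / 9)
        assert stat == pytest.approx(expected, rel=1e-6)
        assert dof == 1

    def test_four_groups_three_df(self):
        rng = np.random.default_rng(0)
        groups = {
            f"Q{i}": (rng.exponential(50, 10), rng.integers(0, 2, 10)) for i in range(4)
        }
        _, _, dof = surv.logrank_test(groups)
        assert dof == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            surv.logrank_test({"a": ([1], [1])})


class TestQuartiles:
    def test_eight_values_pair_groups(self):
        labels = surv.quartile_stratify(pd.Series([1, 2, 3, 4, 5, 6, 7, 8]))
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_constant_single_stratum(self, caplog):
        with caplog.at_level("WARNING"):
            labels = surv.quartile_stratify(pd.Series([2.0] * 8))
        assert labels.nunique() == 1
        assert "constant" in caplog.text

    def test_group_sizes_at_n98(self):
        rng = np.random.default_rng(1)
        labels = surv.quartile_stratify(pd.Series(rng.normal(size=98)))
        sizes = labels.value_counts()
        assert sorted(sizes) == [24, 24, 25, 25]

    def test_ties_broken_by_stable_order(self):
        labels = surv.quartile_stratify(pd.Series([1, 1, 1, 1, 2, 2, 2, 2]))
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            surv.cox_fit(
                pd.Series([1.0] * 20, name="x"),
                np.arange(1, 21),
                [1] * 20,
            )

    def test_planted_coefficient_recovered(self):
        cfg = CohortConfig(seed=10, n_patients=500, presentation_effect=-0.5,
                           neoantigen_effect=0.0)
        rng = np.random.default_rng(2)
        cov = pd.DataFrame(
            {
                "neoantigen_count": rng.poisson(4, 500).astype(float),
                "presentation_score": rng.normal(size=500),
            },
            index=[f"P{i}" for i in range(500)],
        )
        clin = generate_outcomes(cov, cfg)
        fit = surv.cox_fit(
            cov["presentation_score"].reset_index(drop=True),
            clin["time_months"],
            clin["event"],
        )
        est = fit.loc["presentation_score", "coef"]
        se = fit.loc["presentation_score", "se"]
        assert est - 1.96 * se <= -0.5 <= est + 1.96 * se

    def test_null_covariate_covers_zero(self):
        cfg = CohortConfig(seed=11, n_patients=500, presentation_effect=0.0,
                           neoantigen_effect=0.0)
        rng = np.random.default_rng(3)
        cov = pd.DataFrame(
            {
                "neoantigen_count": rng.poisson(4, 500).astype(float),
                "presentation_score": rng.normal(size=500),
            },
            index=[f"P{i}" for i in range(500)],
        )
        clin = generate_outcomes(cov, cfg)
        fit = surv.cox_fit(
            cov["presentation_score"].reset_index(drop=True),
            clin["time_months"],
            clin["event"],
        )
        est, se = fit.loc["presentation_score", ["coef", "se"]]
        assert est - 1.96 * se <= 0.0 <= est + 1.96 * se


class TestCD8AStratification:
    def _expr(self, values, patients):
        return pd.DataFrame(
            {f"{p}_T": [v] for p, v in zip(patients, values)}, index=["CD8A"]
        )

    def test_median_rule_even_split(self):
        patients = [f"P{i}" for i in range(10)]
        expr = self._expr(np.arange(1.0, 11.0), patients)
        labels = surv.cd8a_stratify(expr, patients, rule="median")
        assert (labels == "high").sum() == 5

    def test_upper_quartile_rule_at_n98(self):
        patients = [f"P{i}" for i in range(98)]
        rng = np.random.default_rng(4)
        expr = self._expr(rng.normal(size=98), patients)
        labels = surv.cd8a_stratify(expr, patients, rule="upper-quartile")
        assert 22 <= (labels == "high").sum() <= 25

    def test_planted_interaction_recovered(self):
        """Presentation expression predicts outcome only inside the high
        T-cell-infiltration stratum; the stratified log-rank should find it
        there and not in the low stratum, in most replicates."""
        hits_high, hits_low = 0, 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n = 120
            patients = [f"P{i}" for i in range(n)]
            half = n // 2
            strata = pd.Series(["high"] * half + ["low"] * (n - half), index=patients)
            genes = list(surv.PRESENTATION_GENES) + ["CD8A"]
            expr = pd.DataFrame(
                rng.normal(8, 1, size=(len(genes), n)),
                index=genes,
                columns=[f"{p}_T" for p in patients],
            )
            score = expr.loc["HLA-A"].to_numpy()
            score = (score - score.mean()) / score.std()
            clin_parts = []
            for mask, effect in ((np.arange(n) < half, -1.2), (np.arange(n) >= half, 0.0)):
                ids = [p for p, m in zip(patients, mask) if m]
                cov = pd.DataFrame(
                    {
                        "neoantigen_count": np.zeros(len(ids)),
                        "presentation_score": score[mask],
                    },
                    index=ids,
                )
                cfg = CohortConfig(
                    seed=int(rng.integers(2**31)),
                    n_patients=len(ids),
                    presentation_effect=effect,
                    neoantigen_effect=0.0,
                )
                clin_parts.append(generate_outcomes(cov, cfg))
            clin = pd.concat(clin_parts, ignore_index=True)
            out = surv.stratified_survival(expr, clin, strata, genes=("HLA-A",))
            out = out.set_index("stratum")
            if out.loc["high", "logrank_p"] < 0.05:
                hits_high += 1
            if out.loc["low", "logrank_p"] < 0.05:
                hits_low += 1
        assert hits_high > n_rep / 2
        assert hits_low < n_rep / 2

    def test_stratified_skips_small_stratum(self, caplog):
        rng = np.random.default_rng(5)
        patients = [f"P{i}" for i in range(20)]
        genes = list(surv.PRESENTATION_GENES)
        expr = pd.DataFrame(
            rng.normal(8, 1, size=(len(genes), 20)),
            index=genes,
            columns=[f"{p}_T" for p in patients],
        )
        clin = pd.DataFrame(
            {
                "patient_id": patients,
                "event": rng.integers(0, 2, 20),
                "time_months": rng.exponential(40, 20) + 1,
                "group": ["good"] * 10 + ["poor"] * 10,
                "cms_label": ["CMS2"] * 14 + ["CMS3"] * 6,
            }
        )
        with caplog.at_level("INFO"):
            out = surv.cms_stratified_analysis(expr, clin, genes=("HLA-A",), min_n=10)
        assert set(out["stratum"]) == {"CMS2"}
        assert "skipped" in caplog.text


class TestPairedTest:
    def _expr(self, tumor, normal):
        cols = {}
        for i, (t, n) in enumerate(zip(tumor, normal)):
            cols[f"P{i}_T"] = [t]
            cols[f"P{i}_N"] = [n]
        return pd.DataFrame(cols, index=["HLA-A"])

    def test_no_difference(self):
        vals = np.arange(1.0, 9.0)
        diff, p = surv.paired_tumor_normal_test(self._expr(vals, vals), "HLA-A")
        assert diff == 0.0
        assert p == 1.0

    def test_unpaired_sample_rejected(self):
        expr = self._expr([1, 2], [3, 4]).drop(columns=["P1_N"])
        with pytest.raises(ValueError, match="P1_N"):
            surv.paired_tumor_normal_test(expr, "HLA-A")

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            surv.paired_tumor_normal_test(self._expr([1.0], [2.0]), "HLA-A")

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        normal = rng.normal(10, 0.5, 98)
        tumor = normal + rng.normal(-1.0, 0.5, 98)
        diff, p = surv.paired_tumor_normal_test(self._expr(tumor, normal), "HLA-A")
        assert diff < -0.7
        assert p < 1e-6


class TestPCA:
    def _features(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 5)),
            columns=list("abcde"),
            index=[f"P{i}" for i in range(n)],
        )

    def test_variance_ratios_sum_to_one(self):
        _, evr, _ = surv.pca_immune(self._features())
        assert evr.sum() == pytest.approx(1.0)

    def test_correlated_pair_loads_equally_on_pc1(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        feats = pd.DataFrame(
            {
                "a": x,
                "b": x + rng.normal(0, 1e-6, 200),
                "c": rng.normal(0, 0.1, 200),
            }
        )
        _, _, loadings = surv.pca_immune(feats)
        pc1 = loadings.loc["PC1"]
        assert pc1["a"] == pytest.approx(pc1["b"], abs=1e-3)
        assert abs(pc1["a"]) > abs(pc1["c"])

    def test_sign_convention_fixed(self):
        feats = self._features(seed=3)
        _, _, l1 = surv.pca_immune(feats)
        _, _, l2 = surv.pca_immune(feats)
        pd.testing.assert_frame_equal(l1, l2)
        for _, row in l1.iterrows():
            assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            surv.pca_immune(self._features(n=2))
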