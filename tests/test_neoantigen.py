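"""Peptide windows, k-mer enumeration and the differential-affinity rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutanome import neoantigen as neo


class TestAlleleNormalization:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("HLA-A*02:01", "HLA-A*02:01"),
            ("A*02:01", "HLA-A*02:01"),
            ("A0201", "HLA-A*02:01"),
            ("B0702", "HLA-B*07:02"),
            ("HLA-A*02:01:01P", "HLA-A*02:01"),
            ("A*24:02", "HLA-A*24:02"),
        ],
    )
    def test_normalization(self, token, expected):
        assert neo.normalize_allele(token) == expected

    def test_garbage_token_rejected(self):
        with pytest.raises(neo.AlleleParseError, match="02-garbage"):
            neo.normalize_allele("02-garbage")


class TestParseHLA:
    def test_plain_tsv(self, tmp_path):
        p = tmp_path / "hla.tsv"
        p.write_text("P1\tHLA-B*07:02\nP1\tA0201\nP2\tHLA-A*01:01\n")
        out = neo.parse_hla(p)
        assert out["P1"].alleles == ("HLA-B*07:02", "HLA-A*02:01")
        assert out["P2"].alleles == ("HLA-A*01:01",)

    def test_homozygous_collapsed_and_flagged(self, tmp_path):
        p = tmp_path / "hla.tsv"
        p.write_text("P1\tHLA-A*02:01\nP1\tHLA-A*02:01\n")
        gt = neo.parse_hla(p)["P1"]
        assert gt.alleles == ("HLA-A*02:01",)
        assert "HLA-A*02:01" in gt.homozygous

    def test_hlaminer_summary(self, tmp_path):
        p = tmp_path / "miner.txt"
        p.write_text(
            "HLA-A\n1.\n   A*02:01:01P, 1250.0, 1.2e-30\n"
            "2.\n   A*24:02:01P, 900.0, 1e-20\n"
            "HLA-B\n1.\n   B*07:02:01P, 800.0, 1e-10\n"
        )
        gt = neo.parse_hlaminer(p, "P1")
        assert gt.alleles == ("HLA-A*02:01", "HLA-A*24:02", "HLA-B*07:02")


class TestBuildWindow:
    PROT = "".join("ACDEFGHIKLMNPQRSTVWY" * 10)  # 200 aa

    def test_interior_mutation(self):
        ref = self.PROT[49]
        w = neo.build_window(self.PROT, 50, ref, "W" if ref != "W" else "Y")
        assert len(w.mutant_seq) == 21
        assert w.mutated_index == 10
        assert w.wildtype_seq == self.PROT[39:60]

    def test_n_terminal_truncation(self):
        ref = self.PROT[2]
        w = neo.build_window(self.PROT, 3, ref, "W" if ref != "W" else "Y")
        assert w.wildtype_seq == self.PROT[0:13]
        assert len(w.wildtype_seq) == 13
        assert w.mutated_index == 2

    def test_reference_mismatch_raises(self):
        with pytest.raises(neo.RefMismatchError):
            neo.build_window("LLLLLLLLLLLLLLLLLLLLLLLLLLLLLL", 5, "P", "A")

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            neo.build_window("ACDEFGHIKLMNPQRSTVWYACDEF", 26, "A", "G")


class TestKmerEnumeration:
    def _window(self, length, idx):
        wt = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(length))
        alt = "W" if wt[idx] != "W" else "Y"
        mut = wt[:idx] + alt + wt[idx + 1 :]
        return neo.PeptideWindow(mut, wt, idx)

    def test_interior_full_window_38_pairs(self):
        pairs = neo.enumerate_kmer_pairs(self._window(21, 10))
        assert len(pairs) == 38  # 8 + 9 + 10 + 11 k-windows cover the center

    def test_exhaustive_enumeration_oracle(self):
        """Pair count equals a brute-force scan over every k-window."""
        for length, idx in [(21, 10), (21, 0), (21, 20), (13, 2), (15, 14), (8, 3)]:
            w = self._window(length, idx)
            expected = 0
            for k in range(8, 12):
                for s in range(0, length - k + 1):
                    if s <= idx < s + k:
                        expected += 1
            assert len(neo.enumerate_kmer_pairs(w)) == expected

    def test_short_window_single_pair(self):
        assert len(neo.enumerate_kmer_pairs(self._window(8, 3))) == 1

    def test_mutation_at_window_start(self):
        pairs = neo.enumerate_kmer_pairs(self._window(21, 0))
        assert len(pairs) == 4  # one k-mer per length anchored at position 0
        assert all(m[0] != w[0] and m[1:] == w[1:] for m, w in pairs)

    @given(
        length=st.integers(8, 21),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pairs_differ_at_exactly_one_residue(self, length, frac):
        idx = min(int(frac * length), length - 1)
        for mut, wt in neo.enumerate_kmer_pairs(self._window(length, idx)):
            assert len(mut) == len(wt)
            assert sum(a != b for a, b in zip(mut, wt)) == 1


class _FixedPredictor:
    """Maps (peptide, allele) to preset IC50s; default 5000 nM."""

    def __init__(self, table):
        self.table = table

    def predict(self, peptide, allele):
        return self.table.get((peptide, allele), 5000.0)


class TestDifferentialRule:
    GT = neo.HLAGenotype("P1", ("HLA-A*02:01", "HLA-B*07:02"))

    @pytest.mark.parametrize(
        "ic_mut,ic_wt,expected",
        [
            (30.0, 600.0, True),  # strong mutant, weak wild type
            (30.0, 400.0, False),  # wild type binds too well
            (50.0, 600.0, False),  # boundary: mutant must be < 50
            (30.0, 500.0, False),  # boundary: wild type must be > 500
            (49.99, 500.01, True),
        ],
    )
    def test_thresholds_strict(self, ic_mut, ic_wt, expected):
        pred = _FixedPredictor(
            {("MUTPEPTID", "HLA-A*02:01"): ic_mut, ("WTPEPTIDE", "HLA-A*02:01"): ic_wt}
        )
        calls = neo.call_epitopes([("MUTPEPTID", "WTPEPTIDE")], self.GT, pred)
        row = calls[calls["allele"] == "HLA-A*02:01"].iloc[0]
        assert bool(row["immunogenic"]) is expected

    def test_same_allele_binding(self):
        # mutant strong on A*02:01, wild type weak only on B*07:02: no call
        pred = _FixedPredictor(
            {
                ("MUTPEPTID", "HLA-A*02:01"): 20.0,
                ("WTPEPTIDE", "HLA-A*02:01"): 100.0,
                ("MUTPEPTID", "HLA-B*07:02"): 2000.0,
                ("WTPEPTIDE", "HLA-B*07:02"): 2000.0,
            }
        )
        calls = neo.call_epitopes([("MUTPEPTID", "WTPEPTIDE")], self.GT, pred)
        assert not calls["immunogenic"].any()

    def test_count_modes(self):
        pred = _FixedPredictor(
            {
                ("AAAAAAAA", "HLA-A*02:01"): 10.0,
                ("CCCCCCCC", "HLA-A*02:01"): 10000.0,
                ("AAAAAAAA", "HLA-B*07:02"): 10.0,
                ("CCCCCCCC", "HLA-B*07:02"): 10000.0,
            }
        )
        calls = neo.call_epitopes([("AAAAAAAA", "CCCCCCCC")], self.GT, pred)
        calls["gene"] = "G1"
        calls["protein_change"] = "A5C"
        assert neo.count_neoantigens(calls, mode="peptide") == 1
        assert neo.count_neoantigens(calls, mode="event") == 2
        assert neo.count_neoantigens(calls, mode="mutation") == 1

    def test_counts_monotone_in_thresholds(self):
        """Tightening either threshold can only lower the neoantigen count."""
        rng = np.random.default_rng(3)
        gt = self.GT
        pred = neo.ToyAffinityPredictor(mu=6.0)  # permissive so counts are non-zero
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = []
        for _ in range(300):
            wt = "".join(rng.choice(aas, size=9))
            mut = wt[:4] + ("W" if wt[4] != "W" else "Y") + wt[5:]
            pairs.append((mut, wt))
        base = neo.count_neoantigens(neo.call_epitopes(pairs, gt, pred))
        tighter_mut = neo.count_neoantigens(
            neo.call_epitopes(pairs, gt, pred, ic50_mut_max=25.0)
        )
        tighter_wt = neo.count_neoantigens(
            neo.call_epitopes(pairs, gt, pred, ic50_wt_min=1000.0)
        )
        assert base > 0
        assert tighter_mut <= base
        assert tighter_wt <= base

    def test_toy_predictor_deterministic(self):
        p1 = neo.ToyAffinityPredictor()
        p2 = neo.ToyAffinityPredictor()
        v1 = [p1.predict("SIINFEKLL", a) for a in self.GT.alleles]
        v2 = [p2.predict("SIINFEKLL", a) for a in self.GT.alleles]
        assert v1 == v2
        assert all(v > 0 for v in v1)


class TestTabularPredictor:
    def test_lookup_and_missing_pair(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text("peptide\tallele\tic50\nAAAA\tHLA-A*02:01\t42.0\n")
        pred = neo.TabularPredictor(p)
        assert pred.predict("AAAA", "HLA-A*02:01") == 42.0
        with pytest.raises(neo.PredictorError):
            pred.predict("CCCC", "HLA-A*02:01")


class TestExpressionAwareCounts:
    def _epitopes(self):
        return pd.DataFrame(
            {
                "tumor_id": ["T1"] * 5,
                "gene": ["GA", "GA", "GB", "GB", "GC"],
                "protein_change": ["A1C"] * 5,
                "peptide_mut": list("VWXYZ"),
                "peptide_wt": list("vwxyz"),
                "allele": ["HLA-A*02:01"] * 5,
                "ic50_mut": [10.0] * 5,
                "ic50_wt": [900.0] * 5,
                "immunogenic": [True, True, True, False, True],
            }
        )

    def _expression(self, ga, gb, gc):
        return pd.DataFrame(
            {"T1_T": [ga, gb, gc], "T2_T": [5.0, 5.0, 5.0], "T3_T": [6.0, 6.0, 6.0]},
            index=["GA", "GB", "GC"],
        )

    def test_all_expressed_unchanged(self):
        counts = neo.expression_aware_counts(
            self._epitopes(), self._expression(9.0, 9.0, 9.0)
        )
        assert counts["T1"] == 4

    def test_all_silent_zero(self):
        counts = neo.expression_aware_counts(
            self._epitopes(), self._expression(1.0, 1.0, 1.0)
        )
        assert counts["T1"] == 0

    def test_mixed_filter(self):
        # GA expressed, GB and GC silent: only GA's two immunogenic peptides count
        counts = neo.expression_aware_counts(
            self._epitopes(), self._expression(9.0, 1.0, 1.0)
        )
        assert counts["T1"] == 2

    def test_gene_absent_from_matrix_retained(self, caplog):
        expr = self._expression(9.0, 9.0, 9.0).drop(index="GC")
        with caplog.at_level("INFO"):
            counts = neo.expression_aware_counts(self._epitopes(), expr)
        assert counts["T1"] == 4


class TestExtremes:
    def test_all_zero_all_relapsed(self):
        clin = pd.DataFrame(
            {"patient_id": ["A", "B"], "event": [1, 1], "time_months": [5, 6],
             "group": ["poor", "poor"], "cms_label": ["CMS2", "CMS2"]}
        )
        counts = pd.Series({"A": 0, "B": 0})
        out = neo.extremes_summary(counts, clin).set_index("stratum")
        assert out.loc["count==0", "n_relapsed"] == 2
        assert out.loc["count>8", "n_tumors"] == 0

    def test_direction_with_planted_protective_effect(self):
        """With a protective hazard effect per neoantigen, relapse is rarer
        among high-count tumors than zero-count tumors (pooled over many
        simulated cohorts)."""
        from mutanome.config import CohortConfig
        from mutanome.synthetic import generate_outcomes

        rng = np.random.default_rng(1)
        total = {"low": [0, 0], "high": [0, 0]}  # [relapsed, n]
        for rep in range(200):
            counts = rng.poisson(4.0, size=42)
            cov = pd.DataFrame(
                {
                    "neoantigen_count": counts,
                    "presentation_score": np.zeros(42),
                },
                index=[f"P{i}" for i in range(42)],
            )
            cfg = CohortConfig(seed=int(rng.integers(2**31)), neoantigen_effect=-0.3)
            clin = generate_outcomes(cov, cfg)
            ev = clin.set_index("patient_id")["event"]
            low = ev[counts == 0]
            high = ev[counts > 8]
            total["low"][0] += int(low.sum())
            total["low"][1] += len(low)
            total["high"][0] += int(high.sum())
            total["high"][1] += len(high)
        frac_low = total["low"][0] / total["low"][1]
        frac_high = total["high"][0] / total["high"][1]
        assert frac_high < frac_low
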