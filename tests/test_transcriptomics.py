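import math

import numpy as np
import pandas as pd
import pytest

import dopaq
from dopaq.transcriptomics import (
    ExpressionMatrix,
    cat1_specific_set,
    deg_gene_set,
    hypergeometric_enrichment,
    read_gmt,
)


def tiny_matrix(counts, lengths, conditions):
    genes = [f"g{i}" for i in range(len(lengths))]
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=list(conditions)),
        gene_length_bp=pd.Series(lengths, index=genes),
        sample_conditions=conditions,
    )


class TestRpkm:
    def test_closed_form(self):
        # 10 counts on a 1 kb gene in a 1 M-read library -> RPKM 10
        expr = tiny_matrix(
            {"s1": [10, 999_990]}, [1000, 10_000], {"s1": "c"}
        )
        assert expr.rpkm.loc["g0", "s1"] == pytest.approx(10.0)
        assert tiny_matrix({"s1": [0, 100]}, [1000, 1000], {"s1": "c"}).rpkm.loc[
            "g0", "s1"
        ] == 0.0

    def test_library_size_cancellation(self):
        counts = {"s1": [100, 300, 600]}
        expr = tiny_matrix(counts, [500, 1000, 2000], {"s1": "c"})
        doubled = tiny_matrix({"s1": [200, 600, 1200]}, [500, 1000, 2000], {"s1": "c"})
        pd.testing.assert_frame_equal(expr.rpkm, doubled.rpkm)

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        counts = {f"s{j}": rng.integers(0, 500, 50) for j in range(3)}
        expr = tiny_matrix(counts, rng.integers(200, 4000, 50),
                           {f"s{j}": "c" for j in range(3)})
        lib = expr.counts.sum(axis=0)
        recon = (expr.rpkm.mul(expr.gene_length_bp, axis=0) / 1e9).mul(lib, axis=1).sum(axis=0)
        assert np.allclose(recon, lib, rtol=1e-9)

    def test_zero_library_size(self):
        with pytest.raises(ValueError, match="library"):
            _ = tiny_matrix({"s1": [0, 0]}, [1000, 1000], {"s1": "c"}).rpkm


class TestControlRelative:
    def expr(self):
        return tiny_matrix(
            {"t1": [30, 70], "t2": [30, 70], "c1": [10, 90], "c2": [10, 90]},
            [1000, 1000],
            {"t1": "rx", "t2": "rx", "c1": "ctrl", "c2": "ctrl"},
        )

    def test_anchor_values(self):
        expr = self.expr()
        assert dopaq.control_relative(expr, "g0", ["c1", "c2"], ["c1", "c2"]) == 0.0
        assert dopaq.control_relative(expr, "g0", ["t1", "t2"], ["c1", "c2"]) == pytest.approx(
            2.0
        )

    def test_zero_treated_floors_at_minus_one(self):
        expr = tiny_matrix(
            {"t1": [0, 100], "c1": [10, 90]}, [1000, 1000], {"t1": "rx", "c1": "ctrl"}
        )
        assert dopaq.control_relative(expr, "g0", ["t1"], ["c1"]) == pytest.approx(-1.0)

    def test_zero_control_mean_errors(self):
        expr = tiny_matrix(
            {"t1": [5, 95], "c1": [0, 100]}, [1000, 1000], {"t1": "rx", "c1": "ctrl"}
        )
        with pytest.raises(ValueError, match="control mean"):
            dopaq.control_relative(expr, "g0", ["t1"], ["c1"])


class TestCallDeg:
    def test_identical_conditions_flag_nothing(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=(300, 8))
        conditions = {f"s{j}": ("a" if j < 4 else "b") for j in range(8)}
        expr = tiny_matrix(
            {f"s{j}": base[:, j] for j in range(8)}, rng.integers(500, 3000, 300), conditions
        )
        deg = dopaq.call_deg(expr, ("a", "b"))
        assert (deg["flag"] != "ns").sum() <= 3

    def test_planted_recovery_sensitivity_and_fdr(self):
        expr, truth = dopaq.simulate_deg_experiment(dopaq.DegSimParams(seed=0))
        deg = dopaq.call_deg(expr, ("cat1", "control"))
        called = deg_gene_set(deg)
        sens = len(called & truth["cat1"]) / len(truth["cat1"])
        fdr = len(called - truth["cat1"]) / max(len(called), 1)
        assert sens >= 0.9 and fdr <= 0.1

    def test_pseudocount_robustness_on_default_set(self):
        expr, _ = dopaq.simulate_deg_experiment(dopaq.DegSimParams(seed=0))
        flags1 = dopaq.call_deg(expr, ("cat1", "control"), pseudocount=1.0)["flag"]
        flags05 = dopaq.call_deg(expr, ("cat1", "control"), pseudocount=0.5)["flag"]
        assert (flags1 != flags05).sum() <= 2

    def test_single_replicate_rejected(self):
        expr = tiny_matrix(
            {"t1": [5, 95], "c1": [10, 90], "c2": [10, 90]},
            [1000, 1000],
            {"t1": "rx", "c1": "ctrl", "c2": "ctrl"},
        )
        with pytest.raises(ValueError, match="replicates"):
            dopaq.call_deg(expr, ("rx", "ctrl"))


class TestSetSubtraction:
    def deg_table(self, flags):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(flags))],
                "log2fc": 0.0,
                "p": 1.0,
                "adj_p": 1.0,
                "flag": flags,
            }
        )

    def test_empty_second_table_returns_all_first(self):
        d1 = self.deg_table(["up", "down", "ns"])
        d2 = self.deg_table(["ns", "ns", "ns"])
        assert cat1_specific_set(d1, d2) == {"g0", "g1"}

    def test_subset_gives_empty(self):
        d1 = self.deg_table(["up", "ns", "ns"])
        d2 = self.deg_table(["down", "up", "ns"])
        assert cat1_specific_set(d1, d2) == set()

    def test_partition_identity_exact(self):
        d1 = self.deg_table(["up", "down", "up", "ns"])
        d2 = self.deg_table(["ns", "down", "ns", "up"])
        s1, s2 = deg_gene_set(d1), deg_gene_set(d2)
        assert len(s1 - s2) + len(s1 & s2) == len(s1)

    def test_disjoint_universe_rejected(self):
        d1 = self.deg_table(["up"])
        d2 = self.deg_table(["up", "ns"])
        with pytest.raises(ValueError, match="universe"):
            cat1_specific_set(d1, d2)

    def test_planted_recovery_with_contamination_bound(self):
        expr, truth = dopaq.simulate_deg_experiment(dopaq.DegSimParams(seed=3))
        d1 = dopaq.call_deg(expr, ("cat1", "control"))
        d2 = dopaq.call_deg(expr, ("cat2", "control"))
        specific = cat1_specific_set(d1, d2)
        recovery = len(specific & truth["cat1_only"]) / len(truth["cat1_only"])
        contamination = len(specific - truth["cat1_only"]) / max(len(specific), 1)
        assert recovery >= 0.9 and contamination <= 0.1


def hypergeom_oracle(N, K, n, k):
    """Exhaustive upper-tail probability by direct enumeration."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestEnrichment:
    def test_hand_enumerated_example(self):
        universe = {f"g{i}" for i in range(10)}
        category = {f"g{i}" for i in range(4)}
        query = {f"g{i}" for i in range(5)}  # overlap 4
        res = hypergeometric_enrichment(query, {"cat": category}, universe)
        assert res["p"].iloc[0] == pytest.approx(6 / 252, abs=1e-12)

    def test_matches_enumeration_oracle_exhaustively(self):
        for N in (5, 11, 20):
            universe = [f"g{i}" for i in range(N)]
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    category = set(universe[:K])
                    query = set(universe[-n:])
                    k = len(category & query)
                    res = hypergeometric_enrichment(query, {"c": category}, set(universe))
                    assert res["p"].iloc[0] == pytest.approx(
                        hypergeom_oracle(N, K, n, k), abs=1e-12
                    )

    def test_null_and_degenerate_categories(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(5)}
        tiny = {"g99"}
        res = hypergeometric_enrichment(query, {"tiny": tiny, "all": universe}, universe)
        res = res.set_index("category")
        assert res.loc["tiny", "p"] > 0.9
        assert res.loc["all", "p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment({"x"}, {}, {"a", "b"})


class TestDeltaDeltaCt:
    def plate(self, treated_dct, control_dct):
        rows = []
        for sample, dct in (("treated", treated_dct), ("control", control_dct)):
            rows += [
                {"sample": sample, "gene": "tba-1", "ct": 15.0, "melt_peaks": 1},
                {"sample": sample, "gene": "Y45F10D.4", "ct": 17.0, "melt_peaks": 1},
                {"sample": sample, "gene": "target", "ct": 16.0 + dct, "melt_peaks": 1},
            ]
        return pd.DataFrame(rows)

    def test_closed_form_fold(self):
        res = dopaq.delta_delta_ct(self.plate(5.0, 7.0), ["target"])
        assert res["ddct"].iloc[0] == pytest.approx(-2.0)
        assert res["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_identical_samples_give_unit_fold(self):
        res = dopaq.delta_delta_ct(self.plate(3.0, 3.0), ["target"])
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_invariance_under_plate_wide_ct_offset(self):
        plate = self.plate(5.0, 7.0)
        shifted = plate.assign(ct=plate["ct"] + 3.3)
        a = dopaq.delta_delta_ct(plate, ["target"])
        b = dopaq.delta_delta_ct(shifted, ["target"])
        assert a["fold_change"].iloc[0] == pytest.approx(b["fold_change"].iloc[0])

    def test_multipeak_wells_never_contribute(self):
        plate = self.plate(5.0, 7.0)
        # poison one target well with an absurd Ct but flag it multi-peak
        extra = pd.DataFrame(
            [{"sample": "treated", "gene": "target", "ct": 99.0, "melt_peaks": 2}]
        )
        res = dopaq.delta_delta_ct(pd.concat([plate, extra], ignore_index=True), ["target"])
        assert res["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_missing_reference_gene(self):
        plate = self.plate(5.0, 7.0)
        plate = plate[plate["gene"] != "tba-1"]
        with pytest.raises(ValueError, match="tba-1"):
            dopaq.delta_delta_ct(plate, ["target"])


def test_gmt_reader(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\ng_bad\nsetB\tdesc\tg3\n")
    cats = read_gmt(path)
    assert cats == {"setA": {"g1", "g2"}, "setB": {"g3"}}
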