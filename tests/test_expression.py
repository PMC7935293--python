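"""Expression statistics: filters, NB DE test, BH, ASE, qPCR, Mann-Whitney."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pearlmap.expression import (QpcrSet, abundance_filter, ase_combined,
                                 ase_test, bh_adjust, de_call,
                                 differential_expression, mann_whitney,
                                 nb_de_test, neg_delta_cq, presence_filter,
                                 qpcr_expression)


class TestPresenceFilter:
    def _tpm(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_low_expression_gene_excluded(self):
        tpm = self._tpm([[0.5, 0.2, 3.0, 0.0]])
        assert len(presence_filter(tpm)) == 0

    def test_expressed_in_two_samples_retained(self):
        tpm = self._tpm([[2.0, 2.0, 0.0, 0.0]])
        assert list(presence_filter(tpm)) == ["g0"]

    def test_min_samples_zero_keeps_everything(self):
        tpm = self._tpm([[0.0, 0.0], [5.0, 5.0]])
        assert len(presence_filter(tpm, min_samples=0)) == 2

    def test_literal_reading_drops_gene_below_threshold_twice(self):
        tpm = self._tpm([[0.5, 0.2, 3.0, 3.0], [3.0, 0.5, 3.0, 3.0]])
        kept = presence_filter(tpm, literal=True)
        assert list(kept) == ["g1"]


class TestAbundanceFilter:
    def test_ten_percent_rule(self):
        mask = abundance_filter([50, 30, 15, 5])
        assert list(mask) == [True, True, True, False]

    def test_single_transcript_retained(self):
        assert list(abundance_filter([7.0])) == [True]

    def test_exactly_ten_percent_excluded(self):
        assert list(abundance_filter([90.0, 10.0])) == [True, False]


class TestBhAdjust:
    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDeCall:
    @pytest.mark.parametrize("logfc,adj,expected", [
        (-1.54, 3.76e-4, "down"),   # validated down-regulation is called
        (1.49, 0.001, "ns"),        # just under the fold gate
        (3.0, 0.2, "ns"),           # not significant
        (2.0, 0.01, "up"),
    ])
    def test_thresholds(self, logfc, adj, expected):
        assert de_call(logfc, adj) == expected


class TestNbDeTest:
    def _counts(self, rows, names=("a1", "a2", "b1", "b2")):
        return pd.DataFrame(rows, columns=list(names),
                            index=[f"g{i}" for i in range(len(rows))])

    def test_identical_groups_give_null_result(self):
        counts = self._counts([[10, 20, 10, 20], [5, 5, 5, 5]])
        res = nb_de_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert res.loc["g0", "logfc"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["g0", "pvalue"] == pytest.approx(1.0)

    def test_all_zero_gene_is_inert(self):
        counts = self._counts([[0, 0, 0, 0], [8, 9, 10, 11]])
        res = nb_de_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert res.loc["g0", "pvalue"] == 1.0
        assert res.loc["g0", "logfc"] == 0.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(200, (50, 4))
        counts = self._counts(base.tolist())
        counts.iloc[0, :2] = [25, 30]  # ~8-fold down in group A
        res = nb_de_test(counts, ["a1", "a2"], ["b1", "b2"])
        assert res.iloc[0]["pvalue"] < 1e-4
        assert res.iloc[0]["logfc"] < -2

    def test_group_size_validation(self):
        counts = self._counts([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            nb_de_test(counts, ["a1"], ["b1", "b2"])


class TestCausalGeneRecovery:
    def test_power_and_effect_size_over_replicates(self):
        """The NMD-like down-shift is recovered as significant with the right
        sign in most replicates, and its estimated magnitude is unbiased."""
        from pearlmap.simulate import ExprSimParams, simulate_expression

        lfcs, recovered = [], 0
        n_rep = 25
        for seed in range(n_rep):
            sim = simulate_expression(ExprSimParams(n_genes=500, seed=seed))
            mut = [s for s, g in sim.groups.items() if g == "pearl-eye"]
            wt = [s for s, g in sim.groups.items() if g == "wild-type"]
            de = differential_expression(sim.counts, sim.tpm, mut, wt)
            row = de.loc["SLC2A11B"]
            lfcs.append(row["logfc"])
            recovered += (row["adj_p"] < 0.05) and (row["logfc"] < 0)
        assert np.mean(lfcs) == pytest.approx(-1.54, abs=0.15)
        assert recovered >= 0.6 * n_rep


class TestAseTest:
    def test_balanced_counts_null(self):
        rec = ase_test(10, 10)
        assert rec.p_value == pytest.approx(1.0)
        assert rec.fold == 1.0

    def test_eight_two_binomial_tails(self):
        rec = ase_test(8, 2)
        assert rec.p_value == pytest.approx(112 / 1024)
        assert rec.fold == 4.0

    def test_total_loss_of_one_allele(self):
        rec = ase_test(20, 0)
        assert rec.p_value == pytest.approx(2 * 0.5 ** 20, rel=1e-9)
        assert math.isinf(rec.fold)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_in_alleles(self, a, b):
        if a + b == 0:
            return
        assert ase_test(a, b).p_value == pytest.approx(ase_test(b, a).p_value)

    def test_pooling(self):
        recs = [ase_test(16, 4), ase_test(20, 5), ase_test(24, 6)]
        pooled = ase_combined(recs)
        assert (pooled.wildtype_reads, pooled.mutant_reads) == (60, 15)
        assert pooled.p_value == pytest.approx(ase_test(60, 15).p_value)

    def test_pooling_single_record_is_identity(self):
        rec = ase_test(30, 11)
        pooled = ase_combined([rec])
        assert pooled.p_value == rec.p_value

    def test_balanced_records_pool_to_null(self):
        pooled = ase_combined([ase_test(12, 12)] * 3)
        assert pooled.p_value == pytest.approx(1.0)


class TestQpcr:
    def test_neg_delta_cq_examples(self):
        assert neg_delta_cq([25, 25, 25], [20, 20, 20]) == pytest.approx(-5.0)
        assert neg_delta_cq([21.0], [21.0]) == pytest.approx(0.0)
        assert neg_delta_cq([24.1, 24.3, 24.2], [20.0, 20.1, 19.9]) == \
            pytest.approx(-4.2)

    def test_qpcr_expression_table(self):
        rows = []
        for rep in (1, 2, 3):
            rows.append(("s1", "wild-type", "TARGET", rep, 24.0))
            rows.append(("s1", "wild-type", "REF", rep, 20.0))
        q = QpcrSet(pd.DataFrame(rows, columns=["sample", "group", "gene",
                                                "replicate", "cq"]),
                    target_gene="TARGET", reference_gene="REF")
        tab = qpcr_expression(q)
        assert tab.iloc[0]["neg_delta_cq"] == pytest.approx(-4.0)


class TestMannWhitney:
    def test_complete_separation_nine_vs_five(self):
        x = [10, 11, 12, 13, 14, 15, 16, 17, 18]
        y = [1, 2, 3, 4, 5]
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p == pytest.approx(3.35e-3, rel=5e-3)

    def test_complete_tie_single_elements(self):
        u, p = mann_whitney([4.0], [4.0])
        assert u == 0.5 and p == 1.0

    def test_small_separation_formula(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        from scipy.stats import norm
        z = (0 - 2 + 0.5) / math.sqrt(2 * 2 * 5 / 12)
        assert p == pytest.approx(2 * norm.cdf(z))

    def test_invariant_under_sample_swap(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, 6)
        ux, px = mann_whitney(x, y)
        uy, py = mann_whitney(y, x)
        assert ux == uy and px == pytest.approx(py)

    def test_exact_enumeration_is_smaller_for_total_separation(self):
        x = [10, 11, 12, 13, 14, 15, 16, 17, 18]
        y = [1, 2, 3, 4, 5]
        _, p_exact = mann_whitney(x, y, method="exact")
        assert p_exact == pytest.approx(2 / math.comb(14, 9), rel=1e-9)
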