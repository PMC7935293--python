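"""Simulator contracts: determinism, truth structure, noise calibration."""

import numpy as np
import pytest

from pearlmap.simulate import (CohortSimParams, ExprSimParams, TruthRecord,
                               simulate_cohort, simulate_expression,
                               simulate_trios)
from pearlmap.matrix import MISSING


CLEAN = dict(missing_rate=0.0, err_max=0.0, recomb_erosion=0.0)


class TestCohortSimulation:
    def test_clean_cohort_separates_perfectly_at_causal_site(self, small_cohort):
        c = small_cohort
        gm, tr = c.genotypes, c.truth
        k = int(np.flatnonzero((gm.variants["chrom"] == tr.causal_chrom).to_numpy()
                               & (gm.variants["pos"].to_numpy() == tr.causal_pos))[0])
        case_idx = [gm.samples.index(s) for s in c.phenotypes.cases]
        ctrl_idx = [gm.samples.index(s) for s in c.phenotypes.controls]
        assert all(gm.calls[i, k] == 2 for i in case_idx)
        assert all(gm.calls[i, k] != 2 for i in ctrl_idx)

    def test_truth_genotypes_match_invariants(self, small_cohort):
        tr = small_cohort.truth
        for s, g in tr.genotypes.items():
            if s.startswith("PE"):
                assert g == 2
            else:
                assert g in (0, 1)

    def test_same_seed_identical_vcf_bytes(self, tmp_path):
        params = CohortSimParams(n_cases=4, n_controls=4, n_scaffolds=1,
                                 scaffold_length=60_000, sweep_length=8_000,
                                 seed=5)
        a = simulate_cohort(params).write(tmp_path / "a")
        b = simulate_cohort(params).write(tmp_path / "b")
        assert a["vcf"].read_bytes() == b["vcf"].read_bytes()
        assert a["truth"].read_bytes() == b["truth"].read_bytes()

    def test_missingness_calibration(self):
        params = CohortSimParams(n_cases=8, n_controls=8, n_scaffolds=1,
                                 scaffold_length=1_000_000, sweep_length=20_000,
                                 missing_rate=0.05, err_max=0.0, seed=13)
        c = simulate_cohort(params)
        observed = float((c.genotypes.calls == MISSING).mean())
        assert observed == pytest.approx(0.05, abs=0.02)

    def test_truth_record_round_trips_through_json(self, tmp_path, small_cohort):
        path = tmp_path / "truth.json"
        small_cohort.truth.to_json(path)
        back = TruthRecord.from_json(path)
        assert back == small_cohort.truth

    def test_sweep_must_fit_scaffold(self):
        with pytest.raises(ValueError):
            CohortSimParams(scaffold_length=10_000, sweep_length=20_000)

    def test_causal_pos_must_sit_in_sweep(self):
        with pytest.raises(ValueError):
            CohortSimParams(causal_pos=10)

    def test_gq_depth_fields_emitted(self, small_cohort):
        gm = small_cohort.genotypes
        assert gm.dp is not None and gm.gq is not None
        assert gm.gq.max() <= 99

    def test_causal_snp_is_stop_gained_in_reference_model(self, small_cohort):
        from pearlmap.consequence import STOP_GAINED, annotate_snp

        c = small_cohort
        tr = c.truth
        k = c.genotypes.variants.query(
            "chrom == @tr.causal_chrom and pos == @tr.causal_pos").iloc[0]
        ann = annotate_snp(c.transcript, c.reference, tr.causal_chrom,
                           tr.causal_pos, k["ref"], k["alt"])
        assert ann["consequence"] == STOP_GAINED


class TestExpressionSimulation:
    def test_balanced_allele_fraction_recovers_half(self):
        params = ExprSimParams(n_genes=5, n_hets=200,
                               mutant_allele_fraction=0.5, seed=21)
        sim = simulate_expression(params)
        frac = (sim.ase["mutant_reads"]
                / (sim.ase["mutant_reads"] + sim.ase["wildtype_reads"])).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_mean_observed_lfc_matches_truth(self):
        # Monte-Carlo mean of the causal gene's observed log2 fold-change
        obs = []
        for seed in range(50):
            sim = simulate_expression(ExprSimParams(n_genes=50, seed=seed))
            mut = [s for s, g in sim.groups.items() if g == "pearl-eye"]
            wt = [s for s, g in sim.groups.items() if g == "wild-type"]
            a = sim.counts.loc["SLC2A11B", mut].mean()
            b = sim.counts.loc["SLC2A11B", wt].mean()
            obs.append(np.log2((a + 0.5) / (b + 0.5)))
        assert np.mean(obs) == pytest.approx(-1.54, abs=0.15)

    def test_null_parameters_make_groups_exchangeable(self):
        params = ExprSimParams(n_genes=300, causal_gene_lfc=0.0,
                               qpcr_group_shift=0.0, seed=8)
        sim = simulate_expression(params)
        mut = [s for s, g in sim.groups.items() if g == "pearl-eye"]
        wt = [s for s, g in sim.groups.items() if g == "wild-type"]
        ratio = (sim.counts[mut].mean(axis=1).mean()
                 / sim.counts[wt].mean(axis=1).mean())
        assert ratio == pytest.approx(1.0, abs=0.15)
        assert (sim.truth_lfc == 0).all()

    def test_genotype_driven_grouping(self):
        genotypes = {"a": 2, "b": 2, "c": 0, "d": 1, "e": 0, "f": 1}
        sim = simulate_expression(ExprSimParams(n_genes=10, n_hets=2, seed=1),
                                  genotypes=genotypes)
        assert sorted(s for s, g in sim.groups.items() if g == "pearl-eye") == \
            ["a", "b"]
        assert set(sim.ase["individual"]) <= {"d", "f"}

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ExprSimParams(mutant_allele_fraction=0.0)
        with pytest.raises(ValueError):
            ExprSimParams(dispersion=-1.0)


class TestTrioSimulation:
    def test_offspring_counts_obey_transmission(self):
        df = simulate_trios(500, mutant_allele_freq=0.3, seed=2)
        # an offspring can never carry more mutant copies than transmissible
        max_possible = (df["father_gt"] > 0).astype(int) + \
                       (df["mother_gt"] > 0).astype(int)
        assert (df["offspring_gt"] <= max_possible).all()

    def test_affected_implies_homozygous(self):
        df = simulate_trios(500, seed=6)
        assert (df.loc[df["offspring_phenotype"] == "affected",
                       "offspring_gt"] == 2).all()

    def test_positive_trio_count_required(self):
        with pytest.raises(ValueError):
            simulate_trios(0)
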