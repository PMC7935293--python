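"""Shared-homozygosity interval construction and control-based narrowing."""

import numpy as np
import pytest

from pearlmap.finemap import (exclude_control_matches, genes_in_interval,
                              shared_homozygous_intervals)
from pearlmap.matrix import MISSING

from conftest import make_gm


def _case_matrix(calls, positions):
    variants = [("s0", p, "A", "G", 900.0) for p in positions]
    return make_gm(variants, calls)


class TestSharedHomozygousIntervals:
    def test_hand_traced_example(self):
        # sites 100..500: hom-same at 200,300,400; case2 het at 100;
        # cases discordant (hom-ref vs hom-alt) at 500
        calls = [
            [2, 2, 2, 2, 0],
            [1, 2, 2, 2, 0],
            [2, 2, 2, 2, 2],
        ]
        gm = _case_matrix(calls, [100, 200, 300, 400, 500])
        out = shared_homozygous_intervals(gm)
        assert len(out) == 1
        ci = out[0]
        assert (ci.start, ci.end, ci.n_supporting_sites) == (200, 400, 3)
        assert list(ci.shared_alleles) == [2, 2, 2]

    def test_all_qualifying_spans_whole_region(self):
        calls = [[2, 0, 2], [2, 0, 2]]
        out = shared_homozygous_intervals(_case_matrix(calls, [10, 20, 30]))
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (10, 30)
        assert list(out[0].shared_alleles) == [2, 0, 2]

    def test_tolerance_merges_across_one_violation(self):
        # qualifying runs of 3 + 3 separated by one het site
        calls = [
            [2, 2, 2, 1, 2, 2, 2],
            [2, 2, 2, 2, 2, 2, 2],
        ]
        gm = _case_matrix(calls, [10, 20, 30, 40, 50, 60, 70])
        strict = shared_homozygous_intervals(gm, tolerance=0.0)
        assert [(c.start, c.end) for c in strict] == [(10, 30), (50, 70)]
        merged = shared_homozygous_intervals(gm, tolerance=0.5)
        assert [(c.start, c.end) for c in merged] == [(10, 70)]
        assert merged[0].n_supporting_sites == 6

    def test_missing_case_calls_do_not_disqualify(self):
        calls = [[2, MISSING], [MISSING, 2]]
        out = shared_homozygous_intervals(_case_matrix(calls, [10, 20]))
        assert (out[0].start, out[0].end) == (10, 20)

    def test_empty_region_gives_empty_list(self):
        calls = [[2], [2]]
        gm = _case_matrix(calls, [10])
        assert shared_homozygous_intervals(gm, region=("s0", 500, 600)) == []


class TestExcludeControlMatches:
    def _interval(self):
        calls = [[2, 2, 2], [2, 2, 2]]
        return shared_homozygous_intervals(_case_matrix(calls, [200, 300, 400]))[0]

    def test_control_matching_five_prime_run_trims_interval(self):
        ci = self._interval()
        controls = _case_matrix([[2, 2, 1]], [200, 300, 400])
        out = exclude_control_matches(ci, controls)
        assert [(c.start, c.end) for c in out] == [(400, 400)]
        assert out[0].provenance == "after-control-exclusion"

    def test_no_control_match_returns_input_sites(self):
        ci = self._interval()
        controls = _case_matrix([[1, 1, 1], [0, 1, 0]], [200, 300, 400])
        out = exclude_control_matches(ci, controls)
        assert [(c.start, c.end) for c in out] == [(200, 400)]
        assert list(out[0].site_positions) == [200, 300, 400]

    def test_controls_jointly_covering_all_sites_empty_result(self):
        ci = self._interval()
        controls = _case_matrix([[2, 2, 1], [1, 2, 2]], [200, 300, 400])
        assert exclude_control_matches(ci, controls) == []

    def test_single_site_match_ignored_by_default_but_not_strictly(self):
        ci = self._interval()
        controls = _case_matrix([[1, 2, 1]], [200, 300, 400])
        assert [(c.start, c.end) for c in
                exclude_control_matches(ci, controls)] == [(200, 400)]
        strict = exclude_control_matches(ci, controls, min_match_sites=1)
        assert [(c.start, c.end) for c in strict] == [(200, 200), (400, 400)]

    def test_output_sites_subset_of_input(self, small_cohort):
        gm = small_cohort.genotypes
        phen = small_cohort.phenotypes
        tr = small_cohort.truth
        region = ("scaffold00", tr.sweep_start - 5000, tr.sweep_end + 5000)
        for ci in shared_homozygous_intervals(gm.take_samples(phen.cases),
                                              region=region):
            before = set(ci.site_positions.tolist())
            for out in exclude_control_matches(ci, gm.take_samples(phen.controls)):
                assert set(out.site_positions.tolist()) <= before

    def test_control_identical_to_case_haplotype_empties_interval(self):
        ci = self._interval()
        controls = _case_matrix([[2, 2, 2]], [200, 300, 400])
        assert exclude_control_matches(ci, controls) == []


class TestGenesInInterval:
    GFF = """##gff-version 3
s0\tsrc\tgene\t150\t450\t.\t+\t.\tID=gene:inside;Name=INSIDE
s0\tsrc\tgene\t380\t900\t.\t+\t.\tID=gene:straddle;Name=STRADDLE
s0\tsrc\tgene\t600\t800\t.\t+\t.\tID=gene:outside;Name=OUTSIDE
"""

    def test_overlap_semantics(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(self.GFF)
        calls = [[2, 2], [2, 2]]
        ci = shared_homozygous_intervals(_case_matrix(calls, [200, 400]))[0]
        names = {g["name"] for g in genes_in_interval(ci, path)}
        assert names == {"INSIDE", "STRADDLE"}

    def test_empty_gff_gives_no_genes(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        calls = [[2], [2]]
        ci = shared_homozygous_intervals(_case_matrix(calls, [200]))[0]
        assert genes_in_interval(ci, path) == []


def test_finemap_recovers_causal_position_on_clean_cohort(small_cohort):
    gm = small_cohort.genotypes
    phen = small_cohort.phenotypes
    tr = small_cohort.truth
    region = (tr.causal_chrom, tr.sweep_start - 5000, tr.sweep_end + 5000)
    shared = shared_homozygous_intervals(gm.take_samples(phen.cases), region=region)
    refined = []
    for ci in shared:
        refined.extend(exclude_control_matches(ci, gm.take_samples(phen.controls)))
    hits = [ci for ci in refined if ci.contains(tr.causal_pos)]
    assert hits and all(ci.length <= 10_000 for ci in hits)
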