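"""Shared-homozygosity (IBD) fine-mapping of a recessive candidate region.

If the causal mutation arose once, every affected individual should be
homozygous for the founder haplotype across an interval around it.  The
fine-mapper first finds maximal runs of sites where all cases are homozygous
for one common allele, then subtracts sub-runs where any control is
homozygous for that same recorded haplotype — controls that carry the
ancestral flanking sequence trim the interval from the outside in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class CandidateInterval:
    """A scaffold span supported by shared-homozygosity evidence.

    ``site_positions`` are the qualifying (supporting) sites, 1-based;
    ``shared_alleles`` records, per site, the alt-copy count (0 or 2) all
    cases carry there.  ``start``/``end`` span first to last supporting site.
    """

    chrom: str
    start: int
    end: int
    site_positions: np.ndarray
    shared_alleles: np.ndarray
    provenance: str = "case-shared"

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.shared_alleles = np.asarray(self.shared_alleles, dtype=np.int8)
        if self.site_positions.size == 0:
            raise ValueError("a candidate interval needs >= 1 supporting site")
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def n_supporting_sites(self) -> int:
        return int(self.site_positions.size)

    @property
    def length(self) -> int:
        return int(self.end - self.start + 1)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def _qualifying_sites(gm_cases: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mask of sites where every non-missing case call is the same homozygote.

    Sites at which all cases are missing do not qualify (no evidence).
    Returns (qualifies, shared_allele) with shared_allele in {0, 2} where
    defined.
    """
    calls = gm_cases.calls
    present = calls != MISSING
    any_present = present.any(axis=0)
    het = (calls == 1) & present
    no_het = ~het.any(axis=0)
    hom_alt = (calls == 2) & present
    hom_ref = (calls == 0) & present
    all_same = ~(hom_alt.any(axis=0) & hom_ref.any(axis=0))
    qualifies = any_present & no_het & all_same
    shared = np.where(hom_alt.any(axis=0), 2, 0).astype(np.int8)
    return qualifies, shared


def shared_homozygous_intervals(
    gm: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    tolerance: float = 0.0,
) -> list[CandidateInterval]:
    """Maximal runs of sites at which all cases share one homozygous allele.

    Parameters
    ----------
    gm : GenotypeMatrix
        Restricted to *case* samples by the caller.
    region : (chrom, start, end), optional
        Restrict to one scaffold span first; when omitted the matrix must
        already sit on a single scaffold.
    tolerance : float
        Fraction of interior non-qualifying sites a run may absorb; adjacent
        runs are merged greedily left-to-right while the merged span stays at
        or under this fraction.  0 (default) means strict runs.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 cases for shared-homozygosity mapping")
    if region is not None:
        chrom, start, end = region
        gm = gm.region(chrom, start, end)
    else:
        chroms = gm.variants["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError("matrix spans several scaffolds; pass a region")
        chrom = str(chroms[0]) if len(chroms) else ""
    if gm.n_variants == 0:
        return []

    qualifies, shared = _qualifying_sites(gm)
    pos = gm.variants["pos"].to_numpy()

    runs = _bool_runs(qualifies)
    if tolerance > 0 and len(runs) > 1:
        runs = _merge_runs(runs, qualifies, tolerance)

    out = []
    for i, j in runs:
        idx = np.arange(i, j + 1)
        idx = idx[qualifies[idx]]
        out.append(CandidateInterval(
            chrom=chrom,
            start=int(pos[idx[0]]),
            end=int(pos[idx[-1]]),
            site_positions=pos[idx],
            shared_alleles=shared[idx],
            provenance="case-shared",
        ))
    return out


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = None
    for j, v in enumerate(mask):
        if v and i is None:
            i = j
        elif not v and i is not None:
            runs.append((i, j - 1))
            i = None
    if i is not None:
        runs.append((i, len(mask) - 1))
    return runs


def _merge_runs(runs, qualifies, tolerance) -> list[tuple[int, int]]:
    merged = [runs[0]]
    for nxt in runs[1:]:
        i, _ = merged[-1]
        _, j = nxt
        span = qualifies[i:j + 1]
        bad_frac = 1.0 - span.mean()
        if bad_frac <= tolerance:
            merged[-1] = (i, j)
        else:
            merged.append(nxt)
    return merged


def exclude_control_matches(ci: CandidateInterval,
                            gm_controls: GenotypeMatrix,
                            min_match_sites: int = 2) -> list[CandidateInterval]:
    """Subtract control-matching runs from a case-shared interval.

    For each control, maximal runs of supporting sites at which that control
    is homozygous for the recorded shared allele (a missing call neither
    breaks nor supports a run) are removed from the interval at site
    resolution; the remaining consecutive site groups become new intervals.
    Output sites are always a subset of the input's.

    A run must contain at least ``min_match_sites`` matching sites to count
    as evidence of the shared haplotype; the default of 2 keeps an isolated
    miscalled homozygote from deleting a site.  Set to 1 for the strict
    single-site rule.
    """
    sub = gm_controls.region(ci.chrom, ci.start, ci.end)
    pos_to_col = {int(p): j for j, p in enumerate(sub.variants["pos"].to_numpy())}
    n = ci.n_supporting_sites
    excluded = np.zeros(n, dtype=bool)

    for s in range(sub.n_samples):
        status = np.zeros(n, dtype=np.int8)  # 1 match, 0 missing/absent, -1 mismatch
        for k, (p, allele) in enumerate(zip(ci.site_positions, ci.shared_alleles)):
            j = pos_to_col.get(int(p))
            if j is None:
                continue
            call = sub.calls[s, j]
            if call == MISSING:
                continue
            status[k] = 1 if call == allele else -1
        # runs bounded by mismatches; subtract first-match..last-match spans
        seg_start = 0
        for k in range(n + 1):
            if k == n or status[k] == -1:
                seg = status[seg_start:k]
                hits = np.flatnonzero(seg == 1)
                if hits.size >= min_match_sites:
                    # only sites the control demonstrably matches are removed;
                    # an interior missing call is no evidence either way
                    excluded[seg_start + hits] = True
                seg_start = k + 1

    keep = ~excluded
    if not keep.any():
        log.info("control matching covered every supporting site; interval emptied")
        return []
    out = []
    for i, j in _bool_runs(keep):
        out.append(CandidateInterval(
            chrom=ci.chrom,
            start=int(ci.site_positions[i]),
            end=int(ci.site_positions[j]),
            site_positions=ci.site_positions[i:j + 1][keep[i:j + 1]],
            shared_alleles=ci.shared_alleles[i:j + 1][keep[i:j + 1]],
            provenance="after-control-exclusion",
        ))
    return out


def genes_in_interval(ci: CandidateInterval, gff3_path) -> list[dict]:
    """Genes in a GFF3 whose span overlaps the interval (1-based inclusive)."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except EmptyInputError:
        return []
    out = []
    for gene in db.features_of_type("gene"):
        if gene.seqid != ci.chrom:
            continue
        if gene.start <= ci.end and gene.end >= ci.start:
            name = gene.attributes.get("Name", gene.attributes.get("ID", ["?"]))[0]
            out.append({"gene_id": gene.id, "name": name,
                        "start": gene.start, "end": gene.end,
                        "strand": gene.strand})
    return out


def intervals_to_bed(intervals: list[CandidateInterval], path) -> None:
    with open(path, "w") as fh:
        for ci in intervals:
            fh.write(f"{ci.chrom}\t{ci.start - 1}\t{ci.end}\t{ci.provenance}"
                     f";n_sites={ci.n_supporting_sites}\n")
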