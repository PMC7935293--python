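"""Minimal coding-consequence annotation for single-nucleotide substitutions.

Classifies a SNP against a transcript's CDS using the standard genetic code:
stop_gained, stop_lost, missense, synonymous, or noncoding.  This covers the
candidate class for a recessive loss-of-function trait — a point mutation
creating a premature STOP codon — without attempting full effect prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONCODING = "noncoding"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ReferenceMismatchError(ValueError):
    """The VCF ref allele disagrees with the reference sequence."""


@dataclass
class TranscriptModel:
    """Ordered CDS of one transcript on one scaffold.

    ``cds_segments`` are 1-based inclusive genomic spans, ascending by
    position regardless of strand; transcript orientation is handled
    internally.  A CDS length not divisible by 3 is flagged, not fatal.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    incomplete_frame: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        segs = sorted((int(a), int(b)) for a, b in self.cds_segments)
        for (a, b) in segs:
            if a > b:
                raise ValueError(f"CDS segment {a}-{b} inverted")
        for (_, b0), (a1, _) in zip(segs, segs[1:]):
            if a1 <= b0:
                raise ValueError("CDS segments overlap")
        self.cds_segments = segs
        self.incomplete_frame = self.cds_length % 3 != 0

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    def genomic_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        pos = np.concatenate(
            [np.arange(a, b + 1) for a, b in self.cds_segments]
        )
        return pos[::-1] if self.strand == "-" else pos

    def cds_index(self, pos: int) -> int | None:
        """0-based CDS coordinate of a genomic position, or None if outside."""
        offset = 0
        for a, b in self.cds_segments:
            if a <= pos <= b:
                idx = offset + (pos - a)
                if self.strand == "-":
                    return self.cds_length - 1 - idx
                return idx
            offset += b - a + 1
        return None


def _fetch(reference, chrom: str, pos: int) -> str:
    """One base (upper-case, + strand) from a dict-of-strings or pyfaidx.Fasta."""
    return str(reference[chrom][pos - 1]).upper()


def annotate_snp(tm: TranscriptModel, reference, chrom: str, pos: int,
                 ref: str, alt: str) -> dict:
    """Classify a single-nucleotide substitution against one transcript.

    Returns a dict with ``consequence`` plus, for coding changes, the CDS
    position (1-based), codon change and amino-acid change.  Raises
    :class:`ReferenceMismatchError` if ``ref`` disagrees with the reference
    sequence at ``pos``.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide substitutions are classified")
    ref, alt = ref.upper(), alt.upper()
    genome_base = _fetch(reference, chrom, pos)
    if genome_base != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} reference is {genome_base}, VCF says {ref}"
        )
    if chrom != tm.chrom:
        return {"consequence": NONCODING, "transcript_id": tm.transcript_id}
    idx = tm.cds_index(pos)
    if idx is None:
        return {"consequence": NONCODING, "transcript_id": tm.transcript_id}

    codon_i = idx // 3
    within = idx % 3
    gpos = tm.genomic_positions()[codon_i * 3: codon_i * 3 + 3]
    bases = [_fetch(reference, chrom, int(p)) for p in gpos]
    sub = alt
    if tm.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        sub = alt.translate(_COMPLEMENT)
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + sub + ref_codon[within + 1:]

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        cls = STOP_GAINED
    elif ref_aa == "*" and alt_aa != "*":
        cls = STOP_LOST
    elif ref_aa == alt_aa:
        cls = SYNONYMOUS
    else:
        cls = MISSENSE
    return {
        "consequence": cls,
        "transcript_id": tm.transcript_id,
        "cds_pos": idx + 1,
        "codon_change": f"{ref_codon}>{alt_codon}",
        "aa_change": f"{ref_aa}>{alt_aa}",
    }


def transcripts_from_gff3(gff3_path) -> list[TranscriptModel]:
    """Build transcript models from the CDS features of a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for tx in db.features_of_type("mRNA"):
        segs = [(c.start, c.end) for c in db.children(tx, featuretype="CDS")]
        if not segs:
            continue
        out.append(TranscriptModel(
            transcript_id=tx.id, chrom=tx.seqid, strand=tx.strand,
            cds_segments=segs,
        ))
    return out
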