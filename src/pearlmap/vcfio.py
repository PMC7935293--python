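"""Reading and writing multi-sample VCF 4.2 with GT:DP:GQ genotypes.

Reading goes through :mod:`cyvcf2`; writing is a deterministic text emitter so
that identical inputs produce byte-identical files (a contract the simulator
relies on).  Only biallelic records become matrix columns; multiallelic
records are skipped and counted (the upstream caller decides whether that
matters).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    "##source=pearlmap",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class VcfParseError(RuntimeError):
    pass


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file."""
    path = Path(path)
    lines = list(_HEADER_LINES)
    if contig_lengths is None:
        contig_lengths = {}
        for chrom, sub in gm.variants.groupby("chrom", sort=False):
            contig_lengths[str(chrom)] = int(sub["pos"].max())
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples)
    )
    has_dp = gm.dp is not None
    has_gq = gm.gq is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
    chroms = gm.variants["chrom"].to_numpy()
    poss = gm.variants["pos"].to_numpy()
    refs = gm.variants["ref"].to_numpy()
    alts = gm.variants["alt"].to_numpy()
    quals = gm.variants["qual"].to_numpy()
    for j in range(gm.n_variants):
        cells = []
        for i in range(gm.n_samples):
            cell = _GT_STRINGS[int(gm.calls[i, j])]
            if has_dp:
                cell += f":{int(gm.dp[i, j])}"
            if has_gq:
                cell += f":{int(gm.gq[i, j])}"
            cells.append(cell)
        lines.append(
            f"{chroms[j]}\t{int(poss[j])}\t.\t{refs[j]}\t{alts[j]}\t"
            f"{float(quals[j]):.1f}\t.\t.\t{fmt}\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path, multiallelic: str = "skip") -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Parameters
    ----------
    path : str or Path
        Readable VCF (plain or bgzipped) with GT calls; DP/GQ are optional
        and treated as absent when missing from FORMAT.
    multiallelic : {"skip"}
        Records with more than one ALT allele are skipped and counted; no
        splitting is performed.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    calls_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    n_multi = 0
    has_dp = "DP" in {f for f in _format_ids(vcf)}
    has_gq = "GQ" in {f for f in _format_ids(vcf)}

    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_multi += 1
                continue
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            quals.append(rec.QUAL if rec.QUAL is not None else float("nan"))
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = np.asarray(rec.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            calls_cols.append(gt)
            if has_dp:
                d = rec.format("DP")
                d = (np.full(len(samples), -1, dtype=np.int32) if d is None
                     else _int_format(d))
                dp_cols.append(d)
            if has_gq:
                q = rec.format("GQ")
                q = (np.full(len(samples), -1, dtype=np.int32) if q is None
                     else _int_format(q))
                gq_cols.append(q)
    except Exception as exc:
        raise VcfParseError(f"malformed record near #{len(poss) + 1} in {path!r}: {exc}") from exc

    if n_multi:
        log.info("skipped %d multiallelic record(s) in %s", n_multi, path)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    n = len(variants)
    calls = (
        np.stack(calls_cols, axis=1) if n else np.zeros((len(samples), 0), dtype=np.int8)
    )
    dp = np.stack(dp_cols, axis=1) if (has_dp and n) else None
    gq = np.stack(gq_cols, axis=1) if (has_gq and n) else None
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls, dp=dp, gq=gq)


def _int_format(arr) -> np.ndarray:
    """Flatten a cyvcf2 per-sample FORMAT array to int32 with -1 for missing."""
    arr = np.asarray(arr, dtype=float).reshape(-1)
    arr = np.where(np.isnan(arr) | (arr < -1), -1, arr)
    return arr.astype(np.int32)


def _format_ids(vcf) -> list[str]:
    ids = []
    for h in vcf.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT":
            ids.append(info.get("ID"))
    return ids
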