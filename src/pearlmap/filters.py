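"""Ordered variant/genotype filter cascade applied ahead of association mapping.

The cascade runs in a fixed order: (1) keep SNPs only, (2) drop variants
below a site-quality floor, (3) mask genotypes outside the depth window,
(4) mask genotypes below a genotype-quality floor, (5) drop variants with too
much missingness, (6) apply the minor-allele-frequency rule.  The MAF rule
defaults to *retaining* common variants (MAF >= threshold); a ``maf_literal``
switch inverts it to discard them instead (see the methods note for why both
directions exist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class FilterParams:
    snps_only: bool = True
    qual_min: float = 500.0
    dp_min: int = 4
    dp_max: int = 90
    gq_min: int = 20
    max_missing_fraction: float = 0.20
    maf_min: float = 0.10
    maf_literal: bool = False
    naive_impute: bool = False  # fill MISSING with the variant's modal genotype

    def __post_init__(self) -> None:
        if self.dp_min > self.dp_max:
            raise ValueError("dp_min must be <= dp_max")
        for name in ("max_missing_fraction", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class FilterReport:
    """Counts of variants removed / calls masked at each cascade step."""

    n_input: int = 0
    removed_non_snp: int = 0
    removed_qual: int = 0
    calls_masked_dp: int = 0
    calls_masked_gq: int = 0
    removed_missing: int = 0
    removed_maf: int = 0
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_variants", self.n_input),
            ("step1_removed_non_snp", self.removed_non_snp),
            ("step2_removed_low_qual", self.removed_qual),
            ("step3_calls_masked_depth", self.calls_masked_dp),
            ("step4_calls_masked_gq", self.calls_masked_gq),
            ("step5_removed_missingness", self.removed_missing),
            ("step6_removed_maf", self.removed_maf),
            ("output_variants", self.n_output),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @property
    def variants_removed(self) -> int:
        return self.removed_non_snp + self.removed_qual + self.removed_missing + self.removed_maf


def minor_allele_frequency(calls: np.ndarray) -> float:
    """MAF of one variant from alt-copy counts over called chromosomes.

    Raises
    ------
    ValueError
        if every call is missing (the frequency is undefined).
    """
    calls = np.asarray(calls)
    called = calls[calls != MISSING]
    if called.size == 0:
        raise ValueError("minor allele frequency undefined: all calls missing")
    f_alt = called.sum() / (2 * called.size)
    return float(min(f_alt, 1.0 - f_alt))


def _maf_vector(calls: np.ndarray) -> np.ndarray:
    """Vectorised per-variant MAF; NaN where all calls are missing."""
    present = calls != MISSING
    n_called = present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / (2 * n_called)
    f = np.where(n_called == 0, np.nan, f)
    return np.minimum(f, 1.0 - f)


def apply_filters(gm: GenotypeMatrix, fp: FilterParams | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the six-step cascade, in order, and report per-step removals."""
    fp = fp or FilterParams()
    report = FilterReport(n_input=gm.n_variants)

    # step 1: SNPs only
    if fp.snps_only:
        keep = gm.is_snp()
        report.removed_non_snp = int((~keep).sum())
        gm = gm.take_variants(keep)

    # step 2: site quality
    qual = gm.variants["qual"].to_numpy(dtype=float)
    keep = ~(qual < fp.qual_min)  # NaN QUAL (absent) passes
    report.removed_qual = int((~keep).sum())
    gm = gm.take_variants(keep)

    calls = gm.calls.copy()
    # step 3: per-call depth window
    if gm.dp is not None:
        bad = (calls != MISSING) & ((gm.dp < fp.dp_min) | (gm.dp > fp.dp_max))
        report.calls_masked_dp = int(bad.sum())
        calls[bad] = MISSING
    # step 4: per-call genotype quality
    if gm.gq is not None:
        bad = (calls != MISSING) & (gm.gq < fp.gq_min)
        report.calls_masked_gq = int(bad.sum())
        calls[bad] = MISSING
    gm = GenotypeMatrix(variants=gm.variants, samples=gm.samples, calls=calls,
                        dp=gm.dp, gq=gm.gq)

    # step 5: per-variant missingness
    miss_frac = (gm.calls == MISSING).mean(axis=0)
    keep = ~(miss_frac > fp.max_missing_fraction)
    report.removed_missing = int((~keep).sum())
    gm = gm.take_variants(keep)

    # step 6: minor allele frequency
    maf = _maf_vector(gm.calls)
    if fp.maf_literal:
        keep = ~(maf > fp.maf_min)  # the printed exclusion direction
    else:
        keep = maf >= fp.maf_min
    keep &= ~np.isnan(maf)
    report.removed_maf = int((~keep).sum())
    gm = gm.take_variants(keep)

    if fp.naive_impute:
        gm = _impute_modal(gm)

    report.n_output = gm.n_variants
    return gm, report


def _impute_modal(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Fill MISSING calls with each variant's most frequent genotype."""
    calls = gm.calls.copy()
    for j in range(gm.n_variants):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any() or miss.all():
            continue
        vals, counts = np.unique(col[~miss], return_counts=True)
        col[miss] = vals[np.argmax(counts)]
    return GenotypeMatrix(variants=gm.variants, samples=gm.samples, calls=calls,
                          dp=gm.dp, gq=gm.gq)
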