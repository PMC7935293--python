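"""Genome-wide recessive-model exact association scan with Bonferroni control.

Each variant is collapsed to a binary "homozygous for the target allele"
indicator and tested against the case/control labels with Fisher's exact test
on the 2x2 table.  Because the reference assembly may carry the mutant
haplotype, the default coding tests homozygosity for *both* alleles and keeps
the smaller p-value (anti-conservative by at most a factor of two; a
``minor``-allele coding reproduces the conventional single test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .matrix import MISSING, GenotypeMatrix, PhenotypeTable

_REL_TOL = 1.0 + 1e-7  # tables as probable as observed (up to float fuzz) count


@dataclass(frozen=True)
class ScanParams:
    alpha: float = 0.05
    coding: str = "both"  # {"both", "minor"}
    drop_missing: bool = True
    max_gap: int | None = None  # bp gap that breaks a significant region

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.coding not in ("both", "minor"):
            raise ValueError("coding must be 'both' or 'minor'")


@dataclass
class ScanResult:
    results: pd.DataFrame
    n_tests: int
    threshold: float
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise critical p-value alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def recessive_code(calls: np.ndarray, target_allele: str = "alt") -> np.ndarray:
    """1 iff homozygous for the target allele, 0 otherwise; MISSING propagates."""
    calls = np.asarray(calls)
    hom = 2 if target_allele == "alt" else 0
    out = np.where(calls == hom, 1, 0).astype(np.int8)
    out[calls == MISSING] = MISSING
    return out


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table of non-negative integer counts.

    The two-sided p sums hypergeometric probabilities (over tables with the
    observed margins) no larger than the observed table's probability, with a
    1e-7 relative slack against floating-point ties.  A zero margin makes the
    test degenerate; p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return _fisher_cached(a, b, c, d, alternative)


@lru_cache(maxsize=1 << 20)
def _fisher_cached(a: int, b: int, c: int, d: int, alternative: str) -> float:
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (c + d))
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * _REL_TOL].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def _tables_for_coding(coded: np.ndarray, case_mask: np.ndarray) -> tuple[int, int, int, int]:
    present = coded != MISSING
    hom = coded == 1
    a = int((case_mask & present & hom).sum())
    b = int((case_mask & present & ~hom).sum())
    c = int((~case_mask & present & hom).sum())
    d = int((~case_mask & present & ~hom).sum())
    return a, b, c, d


def genome_scan(gm: GenotypeMatrix, phen: PhenotypeTable,
                sp: ScanParams | None = None) -> ScanResult:
    """Recessive Fisher scan over every variant in the matrix.

    Builds, per variant, the 2x2 table cases/controls x hom/not-hom after
    dropping samples with missing calls; ``coding='both'`` tests hom-alt and
    hom-ref and keeps the smaller p.  ``n_tests`` equals the number of
    variants scanned, and significance uses the Bonferroni threshold
    alpha / n_tests.  Significant regions are maximal runs of significant
    variants per scaffold (optionally broken at gaps above ``max_gap``).
    """
    sp = sp or ScanParams()
    case_mask = phen.case_mask(gm.samples)
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError("need at least two samples per phenotype group")

    n_tests = gm.n_variants
    threshold = bonferroni_threshold(sp.alpha, max(n_tests, 1))

    rows = []
    for j in range(n_tests):
        calls = gm.calls[:, j]
        if sp.coding == "both":
            codings = ("alt", "ref")
        else:
            maf_alt = _alt_freq(calls)
            codings = ("alt",) if maf_alt <= 0.5 else ("ref",)
        best = None
        for target in codings:
            tab = _tables_for_coding(recessive_code(calls, target), case_mask)
            if tab[0] + tab[1] == 0 or tab[2] + tab[3] == 0 or \
               tab[0] + tab[2] == 0 or tab[1] + tab[3] == 0:
                p = 1.0
            else:
                p = _fisher_cached(*tab, "two-sided")
            if best is None or p < best[0]:
                best = (p, target, tab)
        p, target, (a, b, c, d) = best
        rows.append((j, p, target, a, b, c, d, p < threshold))

    res = pd.DataFrame(
        rows, columns=["_j", "p", "coding", "case_hom", "case_other",
                       "control_hom", "control_other", "significant"],
    )
    res = pd.concat(
        [gm.variants.reset_index(drop=True), res.drop(columns="_j")], axis=1
    )
    regions = _significant_regions(res, sp.max_gap)
    return ScanResult(results=res, n_tests=n_tests, threshold=threshold, regions=regions)


def _alt_freq(calls: np.ndarray) -> float:
    called = calls[calls != MISSING]
    if called.size == 0:
        return 0.0
    return float(called.sum() / (2 * called.size))


def _significant_regions(res: pd.DataFrame, max_gap: int | None) -> pd.DataFrame:
    sig = res[res["significant"]]
    rows = []
    if sig.empty:
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        if max_gap is None:
            rows.append((chrom, int(pos[0]), int(pos[-1]), len(pos)))
            continue
        start = prev = pos[0]
        count = 1
        for p in pos[1:]:
            if p - prev > max_gap:
                rows.append((chrom, int(start), int(prev), count))
                start, count = p, 0
            prev = p
            count += 1
        rows.append((chrom, int(start), int(prev), count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write significant regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\tn_snps={row.n_snps}\n")
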