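"""Sliding-window nucleotide diversity, Hudson F_ST and pi-ratio sweep scans.

All statistics are computed from called genotypes: per-site nucleotide
diversity is the mean pairwise difference 2k(m-k)/(m(m-1)) over called
chromosomes, and F_ST is the Hudson estimator aggregated as a ratio of sums
across the sites of a window.  A selective sweep that fixed the causal
haplotype in one group depresses that group's diversity, so the ratio
pi_group1 / pi_group2 (wild-type over pearl-eye in the intended use) spikes
in windows overlapping the swept interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class WindowParams:
    size: int = 20_000
    step: int = 4_000
    min_callable_fraction: float = 0.5
    min_group_call_fraction: float = 0.5  # per-site, per-group callability rule

    def __post_init__(self) -> None:
        if self.step > self.size:
            raise ValueError("step must be <= size")
        if not 0.0 <= self.min_callable_fraction <= 1.0:
            raise ValueError("min_callable_fraction must lie in [0, 1]")


def sliding_windows(scaffold_length: int, wp: WindowParams | None = None) -> list[tuple[int, int]]:
    """1-based inclusive [start, end] windows; trailing overhang dropped."""
    wp = wp or WindowParams()
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    out = []
    s = 1
    while s + wp.size - 1 <= scaffold_length:
        out.append((s, s + wp.size - 1))
        s += wp.step
    return out


def pi_site(alt_count: int, called_chromosomes: int) -> float:
    """Per-site diversity: expected pairwise difference among m chromosomes."""
    k, m = alt_count, called_chromosomes
    if m < 2:
        raise ValueError("need at least two called chromosomes")
    if not 0 <= k <= m:
        raise ValueError("alt count outside [0, m]")
    return 2.0 * k * (m - k) / (m * (m - 1))


def hudson_fst_window(p1, p2, n1, n2) -> float:
    """Hudson F_ST over one or more sites, aggregated as a ratio of sums.

    ``p1, p2`` are per-site allele frequencies and ``n1, n2`` the per-site
    chromosome counts in each group.  Returns NaN when the denominator sums
    to zero (no between-group heterozygosity to normalise by).
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    n2 = np.atleast_1d(np.asarray(n2, dtype=float))
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each site needs >= 2 chromosomes per group")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    den_sum = den.sum()
    if den_sum == 0:
        return float("nan")
    return float(num.sum() / den_sum)


def _per_site_stats(gm: GenotypeMatrix, case_mask: np.ndarray,
                    min_call_frac: float) -> pd.DataFrame:
    """Per-variant allele counts, callability and diversity for both groups."""
    out = {}
    for name, mask in (("g1", ~case_mask), ("g2", case_mask)):
        sub = gm.calls[mask]
        present = sub != MISSING
        m = 2 * present.sum(axis=0)
        k = np.where(present, sub, 0).sum(axis=0)
        callable_ = (present.mean(axis=0) >= min_call_frac) & (m >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = 2.0 * k * (m - k) / (m * (m - 1.0))
            freq = k / m
        out[f"m_{name}"] = m
        out[f"k_{name}"] = k
        out[f"freq_{name}"] = freq
        out[f"pi_{name}"] = pi
        out[f"ok_{name}"] = callable_
    df = pd.DataFrame(out)
    df["chrom"] = gm.variants["chrom"].to_numpy()
    df["pos"] = gm.variants["pos"].to_numpy()
    df["callable"] = df["ok_g1"] & df["ok_g2"]
    return df


def window_scan(gm: GenotypeMatrix, phen: PhenotypeTable,
                wp: WindowParams | None = None,
                scaffold_lengths: dict[str, int] | None = None,
                pseudocount: float = 0.0) -> pd.DataFrame:
    """Windowed pi (both groups), Hudson F_ST and pi-ratio across scaffolds.

    Group 1 is controls (wild-type), group 2 cases (pearl-eye); ``pi_ratio``
    is pi_g1 / pi_g2.  Windows whose callable-site fraction falls below
    ``min_callable_fraction`` are dropped; windows containing no variant
    site at all are dropped (there is nothing to estimate from genotypes).
    ``pi_ratio`` is +inf when only the denominator is zero and NaN when both
    are, unless a ``pseudocount`` is given.
    """
    wp = wp or WindowParams()
    case_mask = phen.case_mask(gm.samples)
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("both phenotype groups must be non-empty")
    site = _per_site_stats(gm, case_mask, wp.min_group_call_fraction)

    if scaffold_lengths is None:
        scaffold_lengths = {
            str(c): int(s["pos"].max()) for c, s in site.groupby("chrom", sort=False)
        }

    rows = []
    for chrom, length in scaffold_lengths.items():
        sub = site[site["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        sub = sub.iloc[order]
        pos = pos[order]
        for start, end in sliding_windows(length, wp):
            i0, i1 = np.searchsorted(pos, [start, end + 1])
            n_sites = i1 - i0
            if n_sites == 0:
                continue
            w = sub.iloc[i0:i1]
            ok = w["callable"].to_numpy()
            n_callable = int(ok.sum())
            frac = n_callable / n_sites
            if frac < wp.min_callable_fraction or n_callable == 0:
                continue
            wok = w[ok]
            pi1 = float(wok["pi_g1"].sum() / n_callable)
            pi2 = float(wok["pi_g2"].sum() / n_callable)
            fst = hudson_fst_window(
                wok["freq_g1"].to_numpy(), wok["freq_g2"].to_numpy(),
                wok["m_g1"].to_numpy(), wok["m_g2"].to_numpy(),
            )
            num, den = pi1 + pseudocount, pi2 + pseudocount
            if den > 0:
                ratio = num / den
            elif num > 0:
                ratio = math.inf
            else:
                ratio = math.nan
            rows.append((chrom, start, end, n_sites, n_callable, frac,
                         pi1, pi2, fst, ratio))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "n_callable",
                 "callable_fraction", "pi_g1", "pi_g2", "fst", "pi_ratio"],
    )


def rank_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Attach descending ranks (1 = top) by F_ST and by pi-ratio.

    +inf pi-ratios rank above all finite values; NaN statistics are left
    unranked.
    """
    out = windows.copy()
    out["rank_fst"] = out["fst"].rank(ascending=False, method="min")
    out["rank_pi_ratio"] = out["pi_ratio"].rank(ascending=False, method="min")
    return out
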