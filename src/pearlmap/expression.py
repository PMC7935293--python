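"""Expression-validation statistics for a candidate loss-of-function gene.

Covers the downstream evidence chain for a nonsense allele subject to
nonsense-mediated decay: two-group negative-binomial differential expression
with BH-FDR and fold-change calling, allele-specific expression (ASE) tests
in heterozygotes, transcript presence/abundance filtering, and RT-qPCR
-dCq group comparison with a Mann-Whitney U test.

The differential-expression engine is an exact conditional NB test with a
common (moment-estimated, genome-wide shrunk) dispersion on median-of-ratios
normalised counts — the classic two-group exact strategy — rather than a
re-implementation of any specific external fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest, mannwhitneyu, norm, rankdata
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1.0 + 1e-7
DISPERSION_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# containers

@dataclass
class AseRecord:
    individual: str
    wildtype_reads: int
    mutant_reads: int
    p_value: float
    fold: float


@dataclass
class QpcrSet:
    """Replicate Cq values for a target and a reference gene per sample.

    ``data`` columns: sample, group, gene, replicate, cq.
    """

    data: pd.DataFrame
    target_gene: str
    reference_gene: str

    def __post_init__(self) -> None:
        need = {"sample", "group", "gene", "replicate", "cq"}
        if not need <= set(self.data.columns):
            raise ValueError(f"qPCR table needs columns {sorted(need)}")
        if (self.data["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")

    @classmethod
    def from_tsv(cls, path, target_gene: str, reference_gene: str) -> "QpcrSet":
        return cls(pd.read_csv(path, sep="\t"), target_gene, reference_gene)


# ---------------------------------------------------------------------------
# filtering

def presence_filter(tpm: pd.DataFrame, min_tpm: float = 1.0,
                    min_samples: int = 2, literal: bool = False) -> pd.Index:
    """Genes considered expressed, from a genes x samples TPM matrix.

    Default (conventional) rule: keep genes with TPM >= ``min_tpm`` in at
    least ``min_samples`` samples.  ``literal=True`` applies the inverted
    reading — drop genes that fall below ``min_tpm`` in at least
    ``min_samples`` samples — for comparison.
    """
    if min_samples <= 0:
        return tpm.index
    above = (tpm >= min_tpm).sum(axis=1)
    if literal:
        below = (tpm < min_tpm).sum(axis=1)
        return tpm.index[below < min_samples]
    return tpm.index[above >= min_samples]


def abundance_filter(tpms, min_fraction: float = 0.10) -> np.ndarray:
    """Mask of transcripts holding strictly more than ``min_fraction`` of the
    locus's total abundance."""
    tpms = np.asarray(tpms, dtype=float)
    if tpms.size == 0:
        raise ValueError("need at least one transcript")
    total = tpms.sum()
    if total == 0:
        return np.zeros_like(tpms, dtype=bool)
    return tpms / total > min_fraction


# ---------------------------------------------------------------------------
# negative-binomial differential expression

def median_of_ratios_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Per-sample size factors: median ratio to the geometric-mean gene."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    finite = np.isfinite(logmat).all(axis=1)
    if not finite.any():
        # no gene expressed everywhere; fall back to library-size ratios
        lib = mat.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    ref = logmat[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logmat[finite] - ref, axis=0))
    return sf


def _common_dispersion(norm_counts: np.ndarray, group_a: np.ndarray) -> float:
    """Genome-wide mean of per-gene moment dispersion estimates."""
    a, b = norm_counts[:, group_a], norm_counts[:, ~group_a]
    na, nb = a.shape[1], b.shape[1]
    mu = norm_counts.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = ss / max(na + nb - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (var - mu) / mu ** 2
    phi = phi[np.isfinite(phi) & (mu > 0)]
    if phi.size == 0:
        return DISPERSION_FLOOR
    return float(max(np.clip(phi, 0, None).mean(), DISPERSION_FLOOR))


def _nb_exact_p(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional test of the group-A sum given the total.

    The sum of i.i.d. NB counts in each group is NB with the same success
    probability, so the conditional distribution of the group-A sum given
    the grand total is free of the mean and depends only on the per-group
    shape parameters r = n / phi.
    """
    if total == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    s = np.arange(total + 1)
    logw = (gammaln(s + r_a) - gammaln(s + 1)
            + gammaln(total - s + r_b) - gammaln(total - s + 1))
    logw -= logsumexp(logw)
    w = np.exp(logw)
    p = w[w <= w[s_a] * _REL_TOL].sum()
    return float(min(p, 1.0))


def nb_de_test(counts: pd.DataFrame, group_a: list[str] | np.ndarray,
               group_b: list[str] | np.ndarray) -> pd.DataFrame:
    """Per-gene exact NB test between two sample groups.

    Parameters
    ----------
    counts : genes x samples raw count matrix.
    group_a, group_b : sample name lists (each >= 2 samples).  ``logfc`` is
        log2(mean_A / mean_B) of normalised means with pseudo-count 0.5, so
        pass the mutant group as A to make NMD-driven loss come out negative.

    Returns a frame indexed by gene with ``logfc`` and ``pvalue``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts[group_a + group_b]
    sf = median_of_ratios_size_factors(sub)
    normed = sub.to_numpy(dtype=float) / sf
    is_a = np.array([True] * len(group_a) + [False] * len(group_b))
    phi = _common_dispersion(normed, is_a)

    mean_a = normed[:, is_a].mean(axis=1)
    mean_b = normed[:, ~is_a].mean(axis=1)
    logfc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    sum_a = np.rint(normed[:, is_a].sum(axis=1)).astype(np.int64)
    total = np.rint(normed.sum(axis=1)).astype(np.int64)
    sum_a = np.minimum(sum_a, total)
    pvals = np.ones(len(sub))
    n_a, n_b = is_a.sum(), (~is_a).sum()
    for g in range(len(sub)):
        if total[g] == 0:
            logfc[g] = 0.0
            continue
        pvals[g] = _nb_exact_p(int(sum_a[g]), int(total[g]), n_a, n_b, phi)
    return pd.DataFrame({"logfc": logfc, "pvalue": pvals}, index=sub.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_call(logfc, adj_p, lfc_min: float = 1.5, fdr: float = 0.05):
    """Vectorised {up, down, ns} call from logFC and FDR-adjusted p."""
    logfc = np.atleast_1d(np.asarray(logfc, dtype=float))
    adj_p = np.atleast_1d(np.asarray(adj_p, dtype=float))
    sig = adj_p < fdr
    out = np.where(sig & (logfc >= lfc_min), "up",
                   np.where(sig & (logfc <= -lfc_min), "down", "ns"))
    return out if out.size > 1 else str(out[0])


def differential_expression(counts: pd.DataFrame, tpm: pd.DataFrame,
                            group_a, group_b, min_tpm: float = 1.0,
                            min_samples: int = 2, lfc_min: float = 1.5,
                            fdr: float = 0.05) -> pd.DataFrame:
    """Presence filter + NB exact test + BH + fold-change calling."""
    keep = presence_filter(tpm, min_tpm=min_tpm, min_samples=min_samples)
    res = nb_de_test(counts.loc[keep], group_a, group_b)
    res["adj_p"] = bh_adjust(res["pvalue"].to_numpy())
    res["call"] = de_call(res["logfc"].to_numpy(), res["adj_p"].to_numpy(),
                          lfc_min=lfc_min, fdr=fdr)
    return res


# ---------------------------------------------------------------------------
# allele-specific expression

def ase_test(wildtype_reads: int, mutant_reads: int,
             individual: str = "") -> AseRecord:
    """Exact binomial test of one heterozygote's allele counts against 0.5.

    ``fold`` is max/min of the two counts (inf when one is zero).
    """
    w, m = int(wildtype_reads), int(mutant_reads)
    if w < 0 or m < 0 or w + m < 1:
        raise ValueError("need non-negative counts with total >= 1")
    p = binomtest(w, w + m, 0.5).pvalue
    if min(w, m) == 0:
        fold = math.inf
    else:
        fold = max(w, m) / min(w, m)
    return AseRecord(individual=individual, wildtype_reads=w, mutant_reads=m,
                     p_value=float(p), fold=float(fold))


def ase_combined(records: list[AseRecord]) -> AseRecord:
    """Pool allele counts across individuals and test the pooled table."""
    if not records:
        raise ValueError("need at least one ASE record")
    w = sum(r.wildtype_reads for r in records)
    m = sum(r.mutant_reads for r in records)
    return ase_test(w, m, individual="pooled")


# ---------------------------------------------------------------------------
# RT-qPCR

def neg_delta_cq(target_cqs, reference_cqs) -> float:
    """-dCq for one sample: -(mean target Cq - mean reference Cq).

    Higher values mean more target expression relative to the reference.
    """
    t = np.asarray(target_cqs, dtype=float)
    r = np.asarray(reference_cqs, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("need >= 1 replicate for both genes")
    return float(-(t.mean() - r.mean()))


def qpcr_expression(q: QpcrSet) -> pd.DataFrame:
    """Per-sample -dCq table from a replicate-level qPCR set."""
    rows = []
    for sample, sub in q.data.groupby("sample", sort=False):
        t = sub.loc[sub["gene"] == q.target_gene, "cq"]
        r = sub.loc[sub["gene"] == q.reference_gene, "cq"]
        rows.append((sample, sub["group"].iloc[0],
                     neg_delta_cq(t.to_numpy(), r.to_numpy())))
    return pd.DataFrame(rows, columns=["sample", "group", "neg_delta_cq"])


def mann_whitney(x, y, method: str = "normal") -> tuple[float, float]:
    """Mann-Whitney U with mid-ranks; two-sided p.

    Default p-value uses the normal approximation with continuity correction
    and tie-corrected variance.  ``method='exact'`` enumerates the exact null
    distribution instead (valid without ties).  The reported U is
    min(U1, n1*n2 - U1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2 - r1
    u = min(u1, n1 * n2 - u1)
    if method == "exact":
        p = float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        return float(u), p
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2.0 + 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.cdf(z))
    return float(u), float(p)
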