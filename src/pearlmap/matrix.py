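"""Core in-memory containers: genotype matrix and phenotype table.

Genotype calls are stored as alt-allele copy counts (0, 1, 2) with -1 for
missing, in a samples x variants array.  Coordinates are 1-based inclusive
throughout the user-facing API (VCF convention); any half-open arithmetic is
internal and converted at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1

#: column order of the per-variant metadata frame
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants with per-call depth and genotype quality.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, ref, alt, qual``;
        positions strictly increasing within each scaffold.
    samples : list of str
        Sample identifiers, in call-matrix row order.
    calls : ndarray of int8, shape (n_samples, n_variants)
        Alt-allele copy counts; ``MISSING`` (-1) marks no-calls.
    dp, gq : ndarray or None
        Per-call read depth and genotype quality (same shape as ``calls``);
        ``None`` when the source VCF carried no DP/GQ FORMAT fields.
    """

    variants: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for arr_name in ("dp", "gq"):
            arr = getattr(self, arr_name)
            if arr is not None and arr.shape != self.calls.shape:
                raise ValueError(f"{arr_name} shape differs from calls")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset variants by boolean mask or integer index (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            variants=self.variants.iloc[index],
            samples=list(self.samples),
            calls=self.calls[:, index],
            dp=None if self.dp is None else self.dp[:, index],
            gq=None if self.gq is None else self.gq[:, index],
        )

    def take_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        names = list(names)
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc} not present in matrix") from exc
        return GenotypeMatrix(
            variants=self.variants,
            samples=names,
            calls=self.calls[rows],
            dp=None if self.dp is None else self.dp[rows],
            gq=None if self.gq is None else self.gq[rows],
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Variants on ``chrom`` with start <= pos <= end (1-based inclusive)."""
        mask = (
            (self.variants["chrom"] == chrom).to_numpy()
            & (self.variants["pos"].to_numpy() >= start)
            & (self.variants["pos"].to_numpy() <= end)
        )
        return self.take_variants(mask)

    def is_snp(self) -> np.ndarray:
        """Boolean mask of single-nucleotide substitutions."""
        ref = self.variants["ref"].str
        alt = self.variants["alt"].str
        bases = set("ACGT")
        ok_ref = (ref.len() == 1).to_numpy() & self.variants["ref"].isin(bases).to_numpy()
        ok_alt = (alt.len() == 1).to_numpy() & self.variants["alt"].isin(bases).to_numpy()
        return ok_ref & ok_alt


@dataclass
class PhenotypeTable:
    """Sample -> phenotype label map for a two-group case/control design."""

    labels: dict[str, str]
    case_label: str = "pearl-eye"
    control_label: str = "wild-type"
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {self.case_label, self.control_label}
        bad = {v for v in self.labels.values() if v not in known}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")

    @property
    def cases(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == self.case_label]

    @property
    def controls(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == self.control_label]

    def case_mask(self, samples: Iterable[str]) -> np.ndarray:
        """Boolean case indicator aligned to ``samples``.

        Raises
        ------
        KeyError
            if any sample lacks a phenotype label (configuration error).
        """
        out = []
        for s in samples:
            if s not in self.labels:
                raise KeyError(f"sample {s!r} has no phenotype label")
            out.append(self.labels[s] == self.case_label)
        return np.asarray(out, dtype=bool)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"sample": list(self.labels), "phenotype": list(self.labels.values())}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, case_label: str = "pearl-eye",
                 control_label: str = "wild-type") -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample", "phenotype"} <= set(df.columns):
            raise ValueError("phenotype TSV needs 'sample' and 'phenotype' columns")
        return cls(dict(zip(df["sample"], df["phenotype"])),
                   case_label=case_label, control_label=control_label)


def make_genotype_matrix(
    records: Iterable[tuple[str, int, str, str, float]],
    samples: list[str],
    calls,
    dp=None,
    gq=None,
) -> GenotypeMatrix:
    """Convenience constructor from (chrom, pos, ref, alt, qual) tuples."""
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        calls=np.asarray(calls, dtype=np.int8),
        dp=None if dp is None else np.asarray(dp),
        gq=None if gq is None else np.asarray(gq),
    )
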