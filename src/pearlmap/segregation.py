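"""Pedigree (trio) and diagnostic-marker concordance under a recessive model.

A marker segregates with a fully penetrant recessive trait when affected
individuals — and only they — are homozygous for the mutant allele, and every
trio obeys Mendelian transmission.  No probabilistic resolution is attempted:
any inconsistency is reported as a violation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING

CONCORDANT = "concordant"
MENDELIAN_VIOLATION = "mendelian_violation"
MODEL_VIOLATION = "model_violation"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class TrioRecord:
    """Genotypes (alt-copy counts, MISSING allowed) and offspring phenotype."""

    father_gt: int
    mother_gt: int
    offspring_gt: int
    affected: bool

    def __post_init__(self) -> None:
        for g in (self.father_gt, self.mother_gt, self.offspring_gt):
            if g not in (0, 1, 2, MISSING):
                raise ValueError(f"genotype {g} not in {{0,1,2,MISSING}}")


def _mutant_copies(gt: int, mutant_allele: str) -> int:
    if gt == MISSING:
        return MISSING
    return gt if mutant_allele == "alt" else 2 - gt


def _transmissible(parent_gt: int) -> set[int]:
    """Alleles (as mutant-copy 0/1) a parent can transmit; MISSING -> both."""
    if parent_gt == MISSING:
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[parent_gt]


def trio_check(tr: TrioRecord, mutant_allele: str = "alt") -> str:
    """Classify one trio at one marker.

    Order of precedence: Mendelian violation (offspring impossible given the
    parents, under any completion of missing parental genotypes), then
    recessive-model violation (phenotype inconsistent with homozygosity, or
    an affected offspring whose parent carries no mutant allele), then
    uninformative when missing data prevents the call, else concordant.
    """
    f = _mutant_copies(tr.father_gt, mutant_allele)
    m = _mutant_copies(tr.mother_gt, mutant_allele)
    o = _mutant_copies(tr.offspring_gt, mutant_allele)

    if o != MISSING:
        possible = {a + b for a in _transmissible(f) for b in _transmissible(m)}
        if o not in possible:
            return MENDELIAN_VIOLATION

    if tr.affected and (f == 0 or m == 0):
        return MODEL_VIOLATION
    if o != MISSING:
        if tr.affected and o != 2:
            return MODEL_VIOLATION
        if not tr.affected and o == 2:
            return MODEL_VIOLATION

    if MISSING in (f, m, o):
        return UNINFORMATIVE
    return CONCORDANT


def check_trio_table(table: pd.DataFrame, mutant_allele: str = "alt") -> pd.DataFrame:
    """Apply :func:`trio_check` to a table with columns
    father_gt, mother_gt, offspring_gt, offspring_phenotype."""
    out = table.copy()
    statuses = []
    for row in table.itertuples(index=False):
        tr = TrioRecord(
            father_gt=int(row.father_gt), mother_gt=int(row.mother_gt),
            offspring_gt=int(row.offspring_gt),
            affected=str(row.offspring_phenotype) == "affected",
        )
        statuses.append(trio_check(tr, mutant_allele))
    out["status"] = statuses
    return out


def marker_concordance(genotypes: dict[str, int], phenotypes: dict[str, bool],
                       mutant_allele: str = "alt") -> dict:
    """Recessive-model concordance of a diagnostic marker across samples.

    affected <=> homozygous mutant.  Samples with a missing genotype are
    tallied separately and excluded from the concordance counts.

    Returns a dict with ``concordant``/``discordant``/``missing`` counts, the
    2x2 genotype-class x phenotype table, and a per-sample frame.
    """
    if set(genotypes) != set(phenotypes):
        raise ValueError("genotypes and phenotypes must cover the same samples")
    rows = []
    table = np.zeros((2, 2), dtype=int)  # [affected?][hom-mutant?]
    n_conc = n_disc = n_miss = 0
    for s in genotypes:
        g = genotypes[s]
        affected = bool(phenotypes[s])
        if g == MISSING:
            rows.append((s, g, affected, "missing"))
            n_miss += 1
            continue
        hom_mut = _mutant_copies(g, mutant_allele) == 2
        table[int(affected), int(hom_mut)] += 1
        if affected == hom_mut:
            n_conc += 1
            rows.append((s, g, affected, "concordant"))
        else:
            n_disc += 1
            rows.append((s, g, affected, "discordant"))
    per_sample = pd.DataFrame(rows, columns=["sample", "genotype", "affected", "status"])
    return {"concordant": n_conc, "discordant": n_disc, "missing": n_miss,
            "table": table, "per_sample": per_sample}
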