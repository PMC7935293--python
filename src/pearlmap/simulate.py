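"""Truth-known cohort, expression, and trio simulators.

The cohort generator emulates a case/control resequencing design for a fully
penetrant recessive trait that swept to fixation in the case group: a base
population of unlinked biallelic SNPs (infinite-sites style, derived-allele
frequencies drawn from a neutral-like 1/f spectrum), a causal nonsense allele
embedded on a founder haplotype that every case carries in two copies, and
identity-by-descent erosion of that haplotype by a geometric recombination
model at each flank.  Genotype observation noise (depth, miscalls, genotype
quality, missingness) mimics medium-coverage sequencing.

The expression generator produces NB counts in which the causal gene is
down-regulated in mutant homozygotes (NMD-like), heterozygote allele counts
skewed against the mutant allele, and qPCR Cq replicates separating the
phenotype groups.  All randomness flows from one seed through one generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import TranscriptModel
from .matrix import MISSING, GenotypeMatrix, PhenotypeTable
from .vcfio import write_vcf

CAUSAL_GENE = "SLC2A11B"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class CohortSimParams:
    """Study-design and noise parameters for the cohort simulator.

    Sample sizes and mean depth follow the two-phenotype pigeon design the
    package targets (23 affected, 26 unaffected, ~11.5x coverage); genome
    size is desk-scale.  ``theta`` is per-bp Watterson diversity of the base
    population; ``recomb_erosion`` is the per-bp per-haplotype probability
    that founder-haplotype identity is truncated at each flank of the causal
    site.
    """

    n_cases: int = 23
    n_controls: int = 26
    n_scaffolds: int = 4
    scaffold_length: int = 400_000
    theta: float = 0.003
    sweep_length: int = 20_000
    causal_scaffold: int = 0
    causal_pos: int | None = None  # default: centre of the sweep interval
    carrier_freq_controls: float = 0.2
    mean_depth: float = 11.5
    err_max: float = 0.05       # miscall probability at zero depth
    err_decay: float = 0.35     # exponential decay of miscall prob per read
    missing_rate: float = 0.02
    recomb_erosion: float = 1e-5
    n_virtual: int = 100        # truncation 1/(2N) of the frequency spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_scaffolds,
               self.scaffold_length, self.sweep_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        for name in ("carrier_freq_controls", "missing_rate", "err_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sweep_length > self.scaffold_length:
            raise ValueError("sweep interval exceeds the scaffold")
        if not 0 <= self.causal_scaffold < self.n_scaffolds:
            raise ValueError("causal_scaffold out of range")
        if self.causal_pos is not None:
            s0, s1 = self.sweep_span()
            if not s0 <= self.causal_pos <= s1:
                raise ValueError("causal_pos must lie within the sweep span")

    def sweep_span(self) -> tuple[int, int]:
        start = (self.scaffold_length - self.sweep_length) // 2 + 1
        return start, start + self.sweep_length - 1

    def causal_position(self) -> int:
        if self.causal_pos is not None:
            return self.causal_pos
        s0, s1 = self.sweep_span()
        return (s0 + s1) // 2


@dataclass(frozen=True)
class ExprSimParams:
    """Expression-simulation parameters.

    Defaults mirror the validated effect sizes for an NMD-degraded nonsense
    allele: log2 fold-change -1.54 in mutant homozygotes and a mutant-allele
    read fraction of 0.2 (>= 4-fold allelic imbalance) in heterozygotes.
    """

    n_genes: int = 2000
    n_wildtype: int = 4
    n_mutant: int = 2
    n_hets: int = 3
    causal_gene_lfc: float = -1.54
    dispersion: float = 0.05
    base_mean: float = 200.0          # scale of the lognormal mean spectrum
    causal_base_mean: float = 500.0   # wild-type mean of the causal gene
    mutant_allele_fraction: float = 0.2
    ase_mean_depth: float = 120.0
    qpcr_group_shift: float = 2.5     # Cq units added in mutant homozygotes
    qpcr_replicates: int = 3
    n_qpcr_wildtype: int = 9
    n_qpcr_mutant: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 < self.mutant_allele_fraction < 1.0:
            raise ValueError("mutant_allele_fraction must lie in (0, 1)")
        if min(self.n_wildtype, self.n_mutant) < 2:
            raise ValueError("need group sizes >= 2 for count simulation")
        if self.qpcr_replicates < 1:
            raise ValueError("need >= 1 qPCR replicate")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort (and optionally its expression)."""

    causal_chrom: str
    causal_pos: int
    sweep_start: int
    sweep_end: int
    causal_gene: str
    genotypes: dict[str, int]                      # true causal genotype
    haplotype_intervals: dict[str, list]           # per sample, per haplotype
    gene_lfc: dict[str, float] = field(default_factory=dict)
    mutant_allele_fraction: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: TruthRecord
    reference: dict[str, str]
    transcript: TranscriptModel
    contig_lengths: dict[str, int]

    def write(self, outdir) -> dict[str, Path]:
        """Write VCF, phenotype TSV, truth JSON, reference FASTA and GFF3."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "truth.json",
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
        }
        write_vcf(self.genotypes, paths["vcf"], self.contig_lengths)
        self.phenotypes.to_tsv(paths["phenotypes"])
        self.truth.to_json(paths["truth"])
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        _write_gene_gff3(self.transcript, paths["gff3"])
        return paths


def _scaffold_name(i: int) -> str:
    return f"scaffold{i:02d}"


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def simulate_cohort(params: CohortSimParams | None = None) -> SimulatedCohort:
    """Simulate a two-phenotype cohort with a recessive swept causal allele.

    Every case is homozygous for the causal allele and identical by descent
    across an (eroded) founder-haplotype interval; controls carry at most one
    copy.  Returns genotypes (with DP/GQ noise applied), phenotypes, truth,
    the reference sequences, and a transcript model in which the causal SNP
    is a stop-gained substitution.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_cases + params.n_controls
    n_hap = 2 * n
    L = params.scaffold_length
    a_n = _harmonic(n_hap)
    lo = 1.0 / (2 * params.n_virtual)
    hi = 1.0 - lo

    controls = [f"WT{i + 1:02d}" for i in range(params.n_controls)]
    cases = [f"PE{i + 1:02d}" for i in range(params.n_cases)]
    samples = controls + cases
    case_rows = np.array([False] * params.n_controls + [True] * params.n_cases)

    sweep_start, sweep_end = params.sweep_span()
    causal_pos = params.causal_position()
    causal_chrom = _scaffold_name(params.causal_scaffold)

    # sweep-haplotype carrier status per haplotype (cases: all; controls: one
    # copy with probability carrier_freq_controls)
    hap_is_sweep = np.zeros(n_hap, dtype=bool)
    hap_is_sweep[2 * params.n_controls:] = True
    carrier = rng.random(params.n_controls) < params.carrier_freq_controls
    for i in np.flatnonzero(carrier):
        hap_is_sweep[2 * i] = True

    # erosion: identity interval of each sweep haplotype around the causal site
    n_sweep_haps = int(hap_is_sweep.sum())
    if params.recomb_erosion > 0:
        d_left = rng.geometric(params.recomb_erosion, n_sweep_haps)
        d_right = rng.geometric(params.recomb_erosion, n_sweep_haps)
    else:
        d_left = np.full(n_sweep_haps, L, dtype=np.int64)
        d_right = np.full(n_sweep_haps, L, dtype=np.int64)
    ident_lo = np.maximum(sweep_start, causal_pos - d_left)
    ident_hi = np.minimum(sweep_end, causal_pos + d_right)

    reference: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    rec_frames = []
    call_blocks = []
    truth_intervals: dict[str, list] = {s: [None, None] for s in samples}

    sweep_idx = 0
    hap_interval = {}
    for h in range(n_hap):
        if hap_is_sweep[h]:
            hap_interval[h] = (int(ident_lo[sweep_idx]), int(ident_hi[sweep_idx]))
            sweep_idx += 1
    for i, s in enumerate(samples):
        truth_intervals[s] = [hap_interval.get(2 * i), hap_interval.get(2 * i + 1)]

    for sc in range(params.n_scaffolds):
        chrom = _scaffold_name(sc)
        ref_arr = rng.integers(0, 4, L, dtype=np.int8)
        n_cand = rng.poisson(params.theta * a_n * L)
        pos = np.sort(rng.choice(L, size=min(n_cand, L), replace=False)) + 1

        is_causal_scaffold = sc == params.causal_scaffold
        if is_causal_scaffold:
            tx, forced = _place_causal_gene(ref_arr, causal_pos, chrom)
            # keep random sites off the forced codon bases and the causal site
            pos = pos[~np.isin(pos, np.fromiter(forced, dtype=np.int64))]

        # population derived-allele frequencies: density ~ 1/f on [lo, hi]
        u = rng.random(pos.size)
        freqs = lo * (hi / lo) ** u
        haps = rng.random((n_hap, pos.size)) < freqs

        if is_causal_scaffold:
            # founder haplotype across the sweep interval + the causal site
            in_sweep = (pos >= sweep_start) & (pos <= sweep_end)
            founder = rng.random(pos.size) < freqs  # only in_sweep entries used
            for h in range(n_hap):
                if not hap_is_sweep[h]:
                    continue
                a, b = hap_interval[h]
                cover = in_sweep & (pos >= a) & (pos <= b)
                haps[h, cover] = founder[cover]
            # insert the causal site (background = ancestral everywhere)
            k = int(np.searchsorted(pos, causal_pos))
            pos = np.insert(pos, k, causal_pos)
            haps = np.insert(haps, k, hap_is_sweep, axis=1)

        geno = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))

        # drop sites monomorphic in the sampled cohort
        tot = haps.sum(axis=0)
        poly = (tot > 0) & (tot < n_hap)
        pos, geno = pos[poly], geno[:, poly]

        ref_alleles = ref_arr[pos - 1]
        alt_alleles = (ref_alleles + rng.integers(1, 4, pos.size)) % 4
        if is_causal_scaffold:
            k = int(np.searchsorted(pos, causal_pos))
            # stop-gained construct: reference codon TGG, derived allele A
            alt_alleles[k] = 0  # 'A'
        qual = rng.gamma(8.0, 200.0, pos.size)

        rec_frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_alleles].astype("U1"),
            "alt": _BASES[alt_alleles].astype("U1"),
            "qual": qual,
        }))
        call_blocks.append(geno)
        reference[chrom] = _BASES[ref_arr].tobytes().decode("ascii")
        contig_lengths[chrom] = L
        if is_causal_scaffold:
            transcript = tx

    variants = pd.concat(rec_frames, ignore_index=True)
    true_calls = np.concatenate(call_blocks, axis=1)

    calls, dp, gq = _observe(true_calls, params, rng)

    gm = GenotypeMatrix(variants=variants, samples=samples, calls=calls, dp=dp, gq=gq)
    phen = PhenotypeTable(
        {**{s: "wild-type" for s in controls}, **{s: "pearl-eye" for s in cases}}
    )
    k = int(np.flatnonzero((variants["chrom"] == causal_chrom).to_numpy()
                           & (variants["pos"].to_numpy() == causal_pos))[0])
    truth = TruthRecord(
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        sweep_start=sweep_start,
        sweep_end=sweep_end,
        causal_gene=CAUSAL_GENE,
        genotypes={s: int(true_calls[i, k]) for i, s in enumerate(samples)},
        haplotype_intervals={s: [list(iv) if iv else None for iv in v]
                             for s, v in truth_intervals.items()},
    )
    return SimulatedCohort(genotypes=gm, phenotypes=phen, truth=truth,
                           reference=reference, transcript=transcript,
                           contig_lengths=contig_lengths)


def _observe(true_calls: np.ndarray, params: CohortSimParams,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depth/quality/missingness observation model on true genotypes."""
    shape = true_calls.shape
    dp = rng.poisson(params.mean_depth, shape).astype(np.int32)
    if params.err_max > 0:
        p_err = params.err_max * np.exp(-params.err_decay * dp)
        with np.errstate(divide="ignore"):
            gq = np.minimum(np.round(-10.0 * np.log10(p_err)), 99).astype(np.int32)
        flip = rng.random(shape) < p_err
        offset = 1 + (rng.random(shape) < 0.5).astype(np.int8)
        calls = np.where(flip, (true_calls + offset) % 3, true_calls).astype(np.int8)
    else:
        gq = np.full(shape, 99, dtype=np.int32)
        calls = true_calls.astype(np.int8)
    if params.missing_rate > 0:
        calls = calls.copy()
        calls[rng.random(shape) < params.missing_rate] = MISSING
    return calls, dp, gq


def _place_causal_gene(ref_arr: np.ndarray, causal_pos: int, chrom: str
                       ) -> tuple[TranscriptModel, set[int]]:
    """Drop a three-exon gene onto the scaffold so the causal SNP is a
    mid-codon G>A nonsense substitution (TGG -> TAG) in exon 3.

    Mutates ``ref_arr`` in place (start codon, causal codon, terminal stop)
    and returns the transcript model plus the genomic positions whose bases
    were forced (random variant sites are kept off those).
    """
    # exon3 starts so that the causal site is the 2nd base of its codon:
    # CDS offset of exon3 start is 270 (divisible by 3), causal at +100
    exon3_start = causal_pos - 100
    exon3_end = exon3_start + 300 - 1
    exon2_end = exon3_start - 501
    exon2_start = exon2_end - 150 + 1
    exon1_end = exon2_start - 501
    exon1_start = exon1_end - 120 + 1
    segments = [(exon1_start, exon1_end), (exon2_start, exon2_end),
                (exon3_start, exon3_end)]
    if exon1_start < 1 or exon3_end > ref_arr.size:
        raise ValueError("causal gene does not fit on the scaffold")

    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    forced: set[int] = set()

    def force(pos: int, base: str) -> None:
        ref_arr[pos - 1] = idx[base]
        forced.add(pos)

    for p, b in zip((exon1_start, exon1_start + 1, exon1_start + 2), "ATG"):
        force(p, b)
    for p, b in zip((causal_pos - 1, causal_pos, causal_pos + 1), "TGG"):
        force(p, b)
    for p, b in zip((exon3_end - 2, exon3_end - 1, exon3_end), "TAA"):
        force(p, b)
    tx = TranscriptModel(
        transcript_id=f"{CAUSAL_GENE}.t1", chrom=chrom, strand="+",
        cds_segments=segments,
    )
    return tx, forced


def _write_gene_gff3(tx: TranscriptModel, path) -> None:
    gene_start = tx.cds_segments[0][0]
    gene_end = tx.cds_segments[-1][1]
    lines = ["##gff-version 3"]
    lines.append("\t".join(map(str, [
        tx.chrom, "pearlmap", "gene", gene_start, gene_end, ".", tx.strand, ".",
        f"ID=gene:{CAUSAL_GENE};Name={CAUSAL_GENE}",
    ])))
    lines.append("\t".join(map(str, [
        tx.chrom, "pearlmap", "mRNA", gene_start, gene_end, ".", tx.strand, ".",
        f"ID={tx.transcript_id};Parent=gene:{CAUSAL_GENE}",
    ])))
    cds_len = 0
    for i, (a, b) in enumerate(tx.cds_segments, 1):
        phase = (3 - cds_len % 3) % 3
        lines.append("\t".join(map(str, [
            tx.chrom, "pearlmap", "CDS", a, b, ".", tx.strand, phase,
            f"ID=cds:{CAUSAL_GENE}.{i};Parent={tx.transcript_id}",
        ])))
        cds_len += b - a + 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression simulation

@dataclass
class SimulatedExpression:
    counts: pd.DataFrame
    tpm: pd.DataFrame
    groups: dict[str, str]           # sample -> {"wild-type", "pearl-eye"}
    ase: pd.DataFrame                # individual, wildtype_reads, mutant_reads
    qpcr: pd.DataFrame | None = None
    truth_lfc: pd.Series | None = None


def simulate_expression(params: ExprSimParams | None = None,
                        genotypes: dict[str, int] | None = None) -> SimulatedExpression:
    """Simulate RNA-seq counts, heterozygote allele counts and qPCR Cq values.

    Non-causal genes share expected expression across groups; the causal gene
    (first row, named after the target locus) is shifted by
    ``causal_gene_lfc`` in mutant homozygotes.  When ``genotypes`` (sample ->
    causal alt-copy count) is given, group sizes are derived from it:
    homozygous-mutant samples form the mutant group, hets contribute ASE
    records; otherwise the parameter group sizes are used.
    """
    params = params or ExprSimParams()
    rng = np.random.default_rng(params.seed)

    if genotypes is not None:
        mut = [s for s, g in genotypes.items() if g == 2]
        wt = [s for s, g in genotypes.items() if g in (0, 1)]
        hets = [s for s, g in genotypes.items() if g == 1]
        n_wt, n_mut = len(wt), len(mut)
        wt_names, mut_names = wt, mut
        het_names = hets[: params.n_hets] if params.n_hets else hets
    else:
        n_wt, n_mut = params.n_wildtype, params.n_mutant
        wt_names = [f"WTRNA{i + 1}" for i in range(n_wt)]
        mut_names = [f"PERNA{i + 1}" for i in range(n_mut)]
        het_names = [f"HET{i + 1}" for i in range(params.n_hets)]

    genes = [CAUSAL_GENE] + [f"gene{i:04d}" for i in range(1, params.n_genes)]
    base = params.base_mean * rng.lognormal(0.0, 1.0, params.n_genes)
    base[0] = params.causal_base_mean
    lfc = np.zeros(params.n_genes)
    lfc[0] = params.causal_gene_lfc

    samples = wt_names + mut_names
    lib = rng.lognormal(0.0, 0.1, len(samples))
    is_mut = np.array([False] * n_wt + [True] * n_mut)
    mean = np.outer(base, lib)
    mean[:, is_mut] *= 2.0 ** lfc[:, None]
    counts = _nb_draw(mean, params.dispersion, rng)
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    col_tot = counts.sum(axis=0).to_numpy(dtype=float)
    tpm = counts / col_tot * 1e6  # equal effective lengths assumed

    ase_rows = []
    for name in het_names:
        total = max(int(rng.poisson(params.ase_mean_depth)), 1)
        mut_reads = int(rng.binomial(total, params.mutant_allele_fraction))
        ase_rows.append((name, total - mut_reads, mut_reads))
    ase = pd.DataFrame(ase_rows, columns=["individual", "wildtype_reads",
                                          "mutant_reads"])

    qpcr = _simulate_qpcr(params, rng)

    groups = {**{s: "wild-type" for s in wt_names},
              **{s: "pearl-eye" for s in mut_names}}
    return SimulatedExpression(
        counts=counts, tpm=tpm, groups=groups, ase=ase, qpcr=qpcr,
        truth_lfc=pd.Series(lfc, index=genes),
    )


def _nb_draw(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _simulate_qpcr(params: ExprSimParams, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    groups = [("wild-type", params.n_qpcr_wildtype, 0.0),
              ("pearl-eye", params.n_qpcr_mutant, params.qpcr_group_shift)]
    for label, n_samples, shift in groups:
        prefix = "WTQ" if label == "wild-type" else "PEQ"
        for i in range(n_samples):
            sample = f"{prefix}{i + 1:02d}"
            target_mu = rng.normal(24.0 + shift, 0.3)
            ref_mu = rng.normal(20.0, 0.3)
            for gene, mu in ((CAUSAL_GENE, target_mu), ("ACTB", ref_mu)):
                for rep in range(1, params.qpcr_replicates + 1):
                    rows.append((sample, label, gene, rep,
                                 float(mu + rng.normal(0.0, 0.15))))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cq"])


# ---------------------------------------------------------------------------
# trio simulation

def simulate_trios(n_trios: int, mutant_allele_freq: float = 0.5,
                   penetrance: float = 1.0, seed: int = 0,
                   parent_genotypes: tuple[int, int] | None = None) -> pd.DataFrame:
    """Simulate parent-offspring trios under Mendelian transmission.

    Parents are drawn in Hardy-Weinberg proportions at ``mutant_allele_freq``
    (or fixed via ``parent_genotypes``); the offspring phenotype is affected
    iff homozygous mutant, subject to ``penetrance``.  Genotypes are mutant
    (alt) allele copy counts.
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    rng = np.random.default_rng(seed)
    if parent_genotypes is not None:
        fa = np.full(n_trios, parent_genotypes[0])
        mo = np.full(n_trios, parent_genotypes[1])
    else:
        fa = rng.binomial(2, mutant_allele_freq, n_trios)
        mo = rng.binomial(2, mutant_allele_freq, n_trios)
    off = rng.binomial(1, fa / 2.0) + rng.binomial(1, mo / 2.0)
    affected = (off == 2) & (rng.random(n_trios) < penetrance)
    return pd.DataFrame({
        "trio_id": [f"trio{i + 1:04d}" for i in range(n_trios)],
        "father_gt": fa,
        "mother_gt": mo,
        "offspring_gt": off,
        "offspring_phenotype": np.where(affected, "affected", "unaffected"),
    })
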