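# Methods

This note documents the models, estimators and design choices behind
`pearlmap`, in the spirit of a statistical supplement.

## Study design being emulated

A fully penetrant autosomal-recessive pigmentation phenotype segregating in
domestic pigeons: affected (pearl-eye) birds are homozygous for a derived
loss-of-function allele that rose on a single founder haplotype during
domestication, so all affected individuals are identical by descent (IBD)
around the causal site; unaffected (wild-type) birds carry zero or one copy.
The analysis chain localises the locus by (1) a genome-wide recessive exact
association scan, (2) windowed diversity/differentiation sweep scans,
(3) shared-homozygosity fine-mapping, then validates the candidate nonsense
SNP by (4) segregation screens, (5) codon-level consequence annotation and
(6) expression statistics consistent with nonsense-mediated mRNA decay
(NMD): down-regulation of the gene in mutant homozygotes, allelic imbalance
against the mutant allele in heterozygotes, and lower qPCR expression.

## Cohort simulator

The generator is deliberately desk-scale and infinite-sites-like; it is not
a coalescent simulator.

- **Genome.** 4 scaffolds × 400 kb by default. Candidate polymorphic sites
  arrive at Watterson density θ·a_{2n}·L with θ = 0.003/bp (pigeon-like
  diversity); each receives a population derived-allele frequency f drawn
  from a density ∝ 1/f truncated to [1/(2N_v), 1−1/(2N_v)] (N_v = 100), the
  neutral-like frequency spectrum. Haplotypes draw alleles independently per
  site (no background LD); sites monomorphic in the sample are dropped.
- **Sweep.** One founder haplotype is laid across a 20 kb interval centred
  on the causal site. Every case carries two copies; each control carries
  one copy with probability 0.2 (the carrier frequency among wild-type birds
  is not an estimate — it is a free design parameter). IBD identity of each
  copy is eroded independently at each flank at geometric distance with
  per-bp rate 10⁻⁵ (mean ≈ 100 kb per flank; the minimum over the 46 case
  copies makes the all-case shared interval a few kb, inside the 20 kb
  sweep). Outside its retained identity segment a copy reverts to
  independent background draws. The causal site itself is derived on every
  sweep copy and ancestral elsewhere, so cases are homozygous derived and no
  control can be.
- **Observation noise.** Per-call depth is Poisson(11.5). Miscall
  probability decays exponentially with depth, p_err(d) = 0.05·e^(−0.35d)
  (≈9×10⁻⁴ at the mean depth); a miscalled genotype moves to one of the
  other two classes uniformly. GQ = −10·log₁₀ p_err capped at 99, which
  makes the GQ ≥ 20 filter equivalent to p_err ≤ 0.01 (depth ≥ 5). Calls
  are additionally missing completely at random at rate 0.02. Site QUAL is
  Gamma(8, 200) — ~2 % of variants fall below the 500 cutoff, exercising
  that filter without dominating it.
- **Causal gene construct.** A three-exon plus-strand gene (120+150+300 bp
  CDS) is placed so the causal SNP is the middle base of a TGG codon in
  exon 3; the derived G→A allele creates TAG, a premature stop. Start (ATG)
  and terminal stop (TAA) codons are forced into the reference; random
  variant sites are kept off the forced bases.
- **Determinism.** All randomness flows from one `numpy` generator seeded by
  the user; identical parameters give byte-identical VCF/JSON output.

What the simulator does **not** emulate: linkage disequilibrium outside the
sweep, population structure beyond the two labelled groups, indels and
multi-allelic variation, read-level artefacts, reference bias. Passing
truth-recovery tests therefore demonstrates the statistical logic of the
chain, not robustness to every failure mode of real resequencing data.

## Filter cascade

Steps run in a fixed order (SNP → QUAL → depth → GQ → missingness → MAF)
and the report accounts for every removal, so input = output + Σ removals
and the cascade is idempotent. The MAF step *retains* variants with
MAF ≥ 0.1 by default; the switch `maf_literal` inverts the direction for
comparison with pipelines that discard common variants. Missing calls are
left missing by default (downstream tests drop them per variant); a naive
modal-genotype imputation is available but off by default, since imputation
is normally delegated to dedicated phasing software.

## Association scan

Each variant is recessive-coded (1 iff homozygous for the target allele)
and tested with Fisher's exact test; the two-sided p sums hypergeometric
probabilities ≤ the observed table's probability with a 1e−7 relative slack
against floating-point ties. Because a reference assembly may carry the
mutant haplotype, the default `coding="both"` tests homozygosity for each
allele and keeps the smaller p — anti-conservative by at most 2×, and
documented as such; `coding="minor"` restores the single conventional test.
The Bonferroni threshold is α/n with n the number of variants scanned.
Under perfect segregation the attainable minimum is 1/C(n, k) (doubled when
group sizes are equal, since the mirrored table is equally extreme).

## Window statistics

Per-site diversity uses the unbiased mean pairwise difference
2k(m−k)/(m(m−1)) over called chromosomes; F_ST is Hudson's estimator
aggregated as a ratio of sums over the sites of each window. Both are
computed from called genotypes — genotype-likelihood machinery is out of
scope, so absolute values are not comparable to likelihood-based pipelines;
rank-based conclusions are the comparable surface. A site is callable when
each group has ≥ 50 % non-missing calls and ≥ 2 chromosomes; windows with a
callable fraction < 50 % (or no variant site at all) are dropped. The
π-ratio is reported with a +∞ sentinel when only the case diversity is zero
(ranked above all finite values) and NaN when both are; negative Hudson
values are reported unclamped to preserve rank behaviour.

## Fine-mapping

A site *qualifies* when every case with a non-missing call is homozygous for
one common allele. Case-shared intervals are maximal runs of qualifying
sites; a tolerance t allows up to that fraction of interior non-qualifying
sites (runs are merged greedily left to right). The library default is the
strict t = 0; the demo pipeline uses t = 0.05 because residual miscalls
(~10⁻³ per retained call) fragment strict runs in cohorts of ~50 birds.
Control exclusion subtracts, per control, runs of supporting sites at which
that control is homozygous for the recorded shared allele. Two robustness
rules, both consequences of the noise model: an interior missing control
call neither breaks a run nor is itself subtracted (it is no evidence of
sharing), and a run must contain ≥ 2 matching sites (`min_match_sites`) so
that one miscalled homozygote cannot delete a site — set it to 1 for the
strict behaviour. Interval coordinates span first to last supporting site,
a conservative and reproducible convention; the causal site can never be
subtracted because no control is homozygous for the mutant allele.

## Segregation

Trio classification is deterministic with a fixed precedence: Mendelian
violation (offspring impossible under any completion of missing parental
genotypes), then recessive-model violation (affected ⇎ homozygous mutant,
or an affected offspring with a mutant-free parent), then uninformative
when missingness blocks the call. Incomplete penetrance and de novo
mutation are deliberately not modelled.

## Consequence annotation

Only single-nucleotide substitutions in CDS are classified, using the
standard genetic code (minus-strand transcripts are reverse-complemented);
splice, UTR and frameshift effects are out of scope. A ref-allele mismatch
with the reference sequence is a data-integrity error, not a silent skip.

## Expression statistics

- **Differential expression.** Median-of-ratios size factors; per-gene
  moment estimates of NB dispersion averaged into a common dispersion
  (floor 10⁻⁴); a two-sided exact conditional test of the group-A
  normalised-count sum given the total (group sums of i.i.d. NB variables
  share the success probability, so the conditional law depends only on the
  shapes n/φ). log2 fold-changes use normalised group means with a 0.5
  pseudo-count. This is a documented exact-test implementation, assessed by
  calibration and power properties rather than numeric parity with any
  particular fitted-GLM package. On a 2,000-gene null simulation the raw
  p < 0.05 fraction is ≈ 0.05 and BH at 5 % makes ≤ 1 call.
- **Recovery power, honestly stated.** With the default design (4 vs 2
  samples, dispersion 0.05, causal mean 500) the causal gene's logFC
  estimate has SD ≈ 0.29, so a true −1.54 effect is FDR-significant with
  the right sign in ≈ 80 % of replicates, and exceeds a ±1.5 fold-change
  reporting gate only ≈ 55 % of the time. Tests assert the attainable
  bounds (≥ 60 % recovery; mean estimated logFC within ±0.15 of −1.54);
  the demo's recovery check gates on FDR and sign, not the knife-edge
  fold-change cutoff.
- **ASE.** A 2×2 construction for one pair of observed counts against a
  50:50 null is not well defined, so allelic imbalance uses the exact
  binomial test against 0.5 (the equivalent inference target); evidence is
  pooled across heterozygotes by summing counts.
- **qPCR.** Replicate Cq values are averaged per sample; −ΔCq = −(Cq_target
  − Cq_reference) increases with expression. Groups are compared with the
  Mann–Whitney U (mid-ranks, reported U = min(U, n₁n₂ − U)); the default p
  is the continuity-corrected normal approximation with tie-corrected
  variance — for complete separation at n = 9 vs 5 it gives p = 3.35×10⁻³,
  whereas exact enumeration gives ≈ 1.0×10⁻³ (`method="exact"`).

## Problem sizes

Defaults are desk-scale by design: a 1.6 Mb four-scaffold genome
(~22,000 simulated variants, ~10,000 after filtering), 2,000 genes for the
expression null, 500-gene replicates for power checks, 20 replicate cohorts
for recovery properties. These sizes keep every property estimable in
seconds while leaving all estimators identical to what full-genome input
would use.

## Known limitations

No covariates or relatedness correction in the scan; no phasing or
model-based IBD; no isoform-level expression; the exact NB test assumes a
single common dispersion; the window statistics need genotype (not
likelihood) input; trio checks assume full penetrance.
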