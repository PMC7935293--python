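# pearlmap

Tools for mapping a fully penetrant recessive Mendelian trait from
case/control whole-genome genotypes and validating the candidate mutation's
expression consequences — modelled on the localisation of the pigeon
*pearl-eye* locus (a pterin-pigmentation phenotype) to a nonsense mutation in
*SLC2A11B*.

The package is aimed at statistical geneticists who want the full inference
chain as tested, reusable components, exercised end-to-end on synthetic
cohorts with known truth rather than on restricted raw data.

## What it computes

Given a multi-sample VCF, a case/control phenotype table, gene models and
expression data, `pearlmap` provides:

- **Variant filtering** — the ordered cascade: SNPs only; site QUAL ≥ 500;
  per-genotype depth in [4, 90] and GQ ≥ 20 (else missing); per-variant
  missingness ≤ 20 %; minor-allele-frequency rule (MAF ≥ 0.1 retained by
  default).
- **Recessive association scan** — per variant, Fisher's exact test on the
  2×2 table of phenotype × "homozygous for the target allele", with
  family-wise control at the Bonferroni threshold α/n. Significance regions
  are maximal runs of significant SNPs.
- **Sweep scans** — per-site nucleotide diversity π = 2k(m−k)/(m(m−1))
  aggregated in 20 kb windows stepped every 4 kb; Hudson's F_ST as a ratio
  of sums across window sites; and the diversity ratio
  π_wild-type/π_pearl-eye, which spikes where the causal haplotype swept
  through the case group.
- **IBD fine-mapping** — the interval where every case is homozygous for one
  shared haplotype, minus sub-runs where any control is homozygous for that
  same haplotype.
- **Segregation checks** — trio Mendelian/recessive-model concordance and
  diagnostic-marker concordance (affected ⇔ homozygous mutant).
- **Consequence annotation** — codon-level classification of candidate SNPs
  (stop_gained / stop_lost / missense / synonymous / noncoding) from GFF3 +
  FASTA.
- **Expression validation** — negative-binomial exact-test differential
  expression with Benjamini–Hochberg FDR and |log2FC| ≥ 1.5 calling;
  exact binomial allele-specific-expression tests against a 50:50 null;
  RT-qPCR −ΔCq quantification compared between groups with a
  Mann–Whitney U test.
- **Simulation** — truth-known cohorts (sweep haplotype, depth/GQ/missing
  noise at ~11.5× coverage), NMD-like expression data (causal-gene
  log2 fold-change −1.54, 4-fold allelic imbalance in heterozygotes) and
  Mendelian trios.

## Worked example

Simulate a default cohort (26 wild-type + 23 pearl-eye birds, four 400 kb
scaffolds, a 20 kb swept causal haplotype) and run the whole chain:

```sh
pearlmap demo --seed 1 --out demo_out
```

```
PASS    top_snp_in_sweep
PASS    causal_window_top_percent
PASS    finemap_contains_causal
PASS    causal_is_stop_gained
PASS    de_causal_recovered
PASS    ase_rejects_balance
PASS    trios_concordant
```

`demo_out/report.json` holds the numbers behind each check. For seed 1:
the filter cascade keeps 10,387 of 22,208 simulated variants; the scan flags
52 SNPs at the Bonferroni threshold 4.8×10⁻⁶ with the top hit at
`scaffold00:200000` (p = 1.8×10⁻¹³) — exactly the simulated causal site;
the window containing it ranks 1st of 384 by π-ratio; fine-mapping narrows
the candidate region to an interval containing only the simulated
*SLC2A11B* gene model, in which the causal SNP annotates as `stop_gained`
(TGG→TAG); differential expression estimates the causal gene's
log2 fold-change at −1.37 (FDR-adjusted p = 0.025, truth −1.54); pooled
allele-specific expression shows a 4.4-fold deficit of the mutant allele
(p = 8.8×10⁻³⁴); and qPCR −ΔCq values separate the groups completely
(U = 0, p = 3.35×10⁻³).

Every stage is also available separately (`pearlmap simulate|filter|scan|
popgen|finemap|trios|consequence|express`), and as library functions.

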