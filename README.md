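# admixgwas

Family-based BMI GWAS and regulatory-variant prioritization for admixed
cohorts, as one tested, reproducible pipeline.

Admixed family studies — for example Brazilian cohorts with European,
African and Native American ancestry — pose two linked problems: the
association scan must respect pedigree relatedness and population
structure, and the handful of suggestive signals it produces must be
prioritized with functional evidence because the sample is too small for
genome-wide significance alone. `admixgwas` implements both stages:

**Stage I — genetic discovery.** Post-imputation QC (MAF ≥ 1 %, variant and
sample missingness < 10 %, exact Hardy–Weinberg p ≥ 10⁻⁶ in unrelateds,
imputation R² > 0.8), LD pruning and PCA fitted on an unrelated subset and
projected onto relatives, then a two-stage polygenic mixed model.  The
phenotype is fitted once by REML as

y = Xβ + g + e,  g ~ N(0, σ²g·2Φ),  e ~ N(0, σ²e I),

with X spanning sex, age, age² and the first four PCs and Φ the pedigree
kinship matrix.  Decorrelated residuals V^(-1/2)(y − Xβ̂) are rank
inverse-normal transformed and regressed on each dosage (additive model, no
further covariates).  Risk loci are 100-kb windows centered on lead SNPs of
clustered suggestive variants (p < 10⁻⁴), merged when they overlap.

**Stage II — functional prioritization.** Loci are retained if genome-wide
significant (p ≤ 5×10⁻⁸) or supported by an obesity-related GWAS-catalog
record at the same lenient significance (5×10⁻⁸ < p < 10⁻⁴); retained
variants are intersected with 18-state chromatin segmentations of adipose
nuclei (EnhA1/EnhA2 active, EnhG1/EnhG2 genic), linked to target genes via
promoter-capture Hi-C interactions across preadipocyte differentiation
timepoints, fine-mapped with a sum-of-single-effects model (PIPs and 95 %
credible sets), flagged when rare in European panels but common in African
panels and ≥ 1 % in the cohort, and scored for allele-specific transcription
factor binding with PWM scans.

Because cohorts of this kind are rarely public, the package ships a
first-class synthetic-cohort generator: Balding–Nichols founder frequencies,
Dirichlet founder admixture, Mendelian gene dropping through
three-generation pedigrees, a polygenic + planted-causal phenotype, and a
matched regulatory fixture (enhancer track, ibed contacts, catalog table,
population frequencies, motifs) in which one planted variant passes every
evidence layer and decoy variants each violate exactly one.

## Worked example

```sh
admixgwas run-all --seed 4 --out demo_run
```

simulates 60 ten-member families (n = 600, 2,000 variants) with one planted
regulatory variant and four decoys, runs both stages and prints the evidence
funnel:

```
samples	600
variants_simulated	2000
variants_qc_passed	791
variants_tested	791
variants_suggestive	5
variants_genome_wide	1
loci_defined	5
loci_genome_wide	1
loci_catalog_supported	3
loci_retained	4
candidate_variants	4
enhancer_variants	3
variants_with_target_genes	2
ancestry_enriched_variants	1
genomic_control_lambda	1.0666
heritability_estimate	0.4744
```

Reading it top to bottom: 791 of 2,000 simulated variants survive QC (most
losses are the strict imputation-R² filter); five reach p < 10⁻⁴, grouping
into five loci of which four are retained (one genome-wide, three
catalog-supported — the fourth decoy's locus lacks obesity-trait catalog
support and is dropped).  Of the four candidate variants, three sit in
active/genic enhancers (the weak-enhancer decoy falls out), two have
promoter-capture target genes (the contact-free decoy falls out), and
exactly one — the planted variant, with its planted target gene *KCNB1* and
a differential binding motif — is also ancestry-enriched.  λ ≈ 1 says the
two-stage test is calibrated despite the dense families.  The run directory
holds every stage artifact (summary statistics, loci, PC scores, QC report,
the evidence ledger) and `funnel.json`; identical config and seed reproduce
it byte for byte.

Library use mirrors the CLI: `simulate_cohort`, `variant_sample_qc`,
`pca_fit_project`, `fit_polygenic_model`, `test_variants`, `define_loci`,
`catalog_crossref`, `classify_enhancer_overlap`, `assign_target_genes`,
`susie_rss`, `score_allele_motifs`, `run_pipeline`.

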