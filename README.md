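# cagewas

Mixed-model GWAS toolkit for growth and feed-efficiency traits in
group-housed animals, where feed intake exists only as weekly cage totals
and only a minority of cage members are genotyped.

Two scan engines are provided:

* **Per-SNP regression scan** (`gwas-emmax`) for individually recorded
  traits: an animal model with batch / parity / litter-size / cage-size
  fixed effects, independent cage and litter random effects and a
  pedigree-structured additive effect, fitted by maximum likelihood.
  `mode=exact` refits variance components per SNP; `mode=emmax` freezes the
  null covariance and tests each SNP by generalised least squares.
* **Bivariate allele-content scan** (`gwas-bivar`): each SNP's allele
  content is treated as a second trait with covariance `G0 ⊗ A` to the
  performance trait, fitted by (SQUAREM-accelerated) EM-REML. Because
  relatives propagate genotype information through the pedigree, cage-average
  traits (ADFI, FCR, RFI) can be mapped even when most cage members are
  ungenotyped: a cage-mean record carries weight 1/N on each member's
  additive and litter effect and residual variance σ²ₑ/N. The SNP effect is
  recovered as `α = σ_a1,a2 / (2 f (1 − f))` and tested by a χ²(1)
  likelihood-ratio test on the genetic covariance.

Upstream and downstream stages are included: trait derivation from raw
weekly records (ADG, ADFI, FCR, batch-nested RFI, metabolic weight, the
0.75 × 1.10 restricted-ration rule), pedigree relationship matrix, genotype
QC (call rate / missingness / MAF / autosomes), LD r² decay and distance
pruning, Storey pFDR q-values at genome- or chromosome-wide level,
QTL-region merging (<1 Mb gap) with ±1 Mb annotation windows, and a full
synthetic-data generator (pedigree with litters, cages of 6–8 split by
weaning-size class and feeding regime, LD-structured gene-dropped
genotypes, weekly body weights and cage feed, truth file).

## Command line

All commands live under one entry point:

```sh
cagewas simulate --seed 7 --out sim/                 # synthetic dataset
cagewas traits   --bw sim/body_weights.csv --animals sim/animals.csv \
                 --feed sim/cage_feed.csv \
                 --out-individual ind.csv --out-cage cages.csv
cagewas qc       --bfile sim/genotypes --out filtered
cagewas gwas-emmax --bfile filtered --pedigree sim/pedigree.csv \
                 --phenotypes ind.csv --regime F --out adg_emmax.tsv
cagewas gwas-bivar --bfile filtered --pedigree sim/pedigree.csv \
                 --phenotypes ind.csv --cage-phenotypes cages.csv \
                 --trait fcr --out fcr_bivar.tsv
cagewas qvalue   --assoc fcr_bivar.tsv --level chromosome --out fcr_q.tsv
cagewas regions  --assoc fcr_q.tsv --out fcr_regions.tsv --windows-out fcr_windows.tsv
cagewas ld       --bfile filtered --out ld_decay.tsv
```

Thresholds and knobs (QC cut-offs, pFDR level, region gap, EM tolerances,
allele-count orientation, seed) come from a YAML `RunConfig`, passed with
`--config run.yaml`.

Genotypes are read from PLINK bed/bim/fam (allele content counts the bim A1
allele; flip with `count_a1: false`) or from a plain 0/1/2 CSV fallback.
Pedigrees are 3-column CSVs (animal, sire, dam; 0/blank = unknown).

## Package layout

| module | contents |
|---|---|
| `cagewas.io_formats` | bed/bim/fam codec, pedigree/phenotype CSVs, assoc TSV, `RunConfig` |
| `cagewas.pedigree` | topological pedigree, numerator relationship matrix A |
| `cagewas.traits` | ADG, ADFI, FCR, RFI, metabolic weight, ration rule |
| `cagewas.genotype_qc` | QC filters, allele frequencies, LD r², pruning, decay |
| `cagewas.mixed_models` | univariate ML scan, bivariate EM-REML, LRT, effect arithmetic |
| `cagewas.discovery` | Storey q-values, significance flags, QTL regions, windows |
| `cagewas.simdata` | synthetic-data generator and truth file |
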