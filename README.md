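# ovistail

Selection-signature analysis for the sheep fat-tail phenotype.

Fat-tailed sheep store adipose tissue in the tail; the trait arose under
human selection after domestication, while the wild ancestor (Mouflon) and
many modern breeds are thin-tailed. This package implements the genomic
scan used to localize the major locus for the trait: a combined
**F<sub>ST</sub> + ΔDAF** screen over worldwide breed panels of 50K-array
genotypes, followed by a sequence-level analysis of allele-frequency
differentiation and haplotype structure inside candidate genes. A
synthetic-data generator with the same statistical structure (Balding–
Nichols drift across breeds, planted selected loci, a wild outgroup) makes
every stage runnable and testable without any external download.

## Method

For each SNP and each pair of one fat-tailed breed *i* and one thin-tailed
breed *j*:

- **F<sub>ST</sub>** is the Weir & Cockerham (1984) variance-components
  estimator θ̂ = a / (a + b + c), computed from genotype counts including
  heterozygotes; pairs monomorphic for the same allele are undefined and
  excluded from averaging rather than counted as zero.
- **ΔDAF** = DAF<sub>fat</sub> − DAF<sub>thin</sub>, the signed difference
  in derived-allele frequency after polarizing alleles against the
  outgroup (ancestral allele = outgroup majority; exact ties are dropped).

Both statistics are averaged over all fat × thin breed pairs of a group
comparison (e.g. Middle-East fat vs South-Asian thin). Within each
comparison the top 1% of each averaged statistic is flagged and a SNP is
*positively selected* when flagged by **both** tests. The candidate set is
the intersection across all comparisons, then filtered for worldwide
consistency: a SNP is removed when DAF > 0.5 in more than ⌊30%⌋ of all
thin-tailed breeds or DAF < 0.5 in more than ⌊30%⌋ of all fat-tailed breeds
(with 18 thin and 14 fat breeds: more than 5, resp. 4). Genes within
±150 kb of surviving SNPs are attached from a BED/GFF3 annotation.

The sequence-level follow-up computes the absolute group allele-frequency
difference |ΔAF| per variant from a (phased) VCF, clusters consecutive
variants with |ΔAF| > 0.6 into elevated regions, exports the per-region
haplotype matrix, and selects high-confidence candidates with |ΔAF| > 0.8
and fat-group DAF > 0.8.

Supporting stages: PLINK text PED/MAP and VCF I/O with panel merging and
allele-registration reconciliation; call-rate/MAF/relatedness QC (PI-HAT by
PLINK-style method of moments, pruning pairs over 0.3); LD pruning, PCA
with breed-level outlier flags, and a neighbor-joining breed tree from
Nei's standard genetic distance.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (library calls only; run them in order from the repository root):

```bash
python analysis/01_simulate_panel.py --seed 42
python analysis/02_quality_control.py
python analysis/03_polarize_alleles.py
python analysis/04_population_structure.py
python analysis/05_selection_scan.py
python analysis/06_region_analysis.py
```

Output of the scan and region stages at seed 42:

```
MEF_vs_SAT: 69 positively selected SNPs (F_ST cutoff 0.192, dDAF cutoff 0.216)
MEF_vs_EUT: 70 positively selected SNPs (F_ST cutoff 0.186, dDAF cutoff 0.209)
CHF_vs_SAT: 78 positively selected SNPs (F_ST cutoff 0.207, dDAF cutoff 0.245)
consensus across all comparisons: 20 loci; 20 survive the breed-consistency filter
planted-locus recovery: 20/20; neutral false positives in consensus: 0
elevated region 1: 15:3854063-3860894 (6.8 kb), 51 SNPs with dAF > 0.6,
haplotype matrix 58 x 122
```

Read: each comparison flags a few dozen SNPs as selected (top-1% of both
statistics), but only the 20 loci planted with high derived-allele
frequency in fat-tailed breeds survive the cross-comparison consensus and
breed-consistency filter — no neutral SNP does. The region stage localizes
a planted divergent haplotype block to its exact 6,832-bp span and exports
the 58-haplotype × 122-variant matrix (fat-tailed haplotypes carry the
alternative background).

The same pipeline runs on real data from one YAML config via the CLI:

```bash
ovistail run-all --config my_study.yaml     # or: ovistail scan / qc / region ...
```

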