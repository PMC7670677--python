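# Methods

## Data model and conventions

Genotypes live in a dense samples × SNPs dosage matrix counting copies of
`allele_b` (0/1/2, −1 missing). `allele_a` is the first allele encountered
in the PED column for a SNP — a deterministic registration that does not
depend on allele frequency, so merging and re-reading never silently flips
dosages (a flip is applied explicitly, x ↦ 2−x, when a second panel is
registered the other way). All coordinates are 1-based inclusive
internally; BED's 0-based half-open intervals are converted at the I/O
boundary. Strand-ambiguous SNPs (A/T, C/G) whose registration conflicts
across merged panels are dropped, not flipped: without strand metadata a
registration flip and a strand error are indistinguishable, and same-
platform chips rarely hit this case.

## Quality control

SNPs are removed when call rate ≤ 0.90 or MAF ≤ 0.05 (both inclusive of
the boundary); samples when call rate < 0.90 (strict). MAF is pooled over
all non-outgroup samples — a per-breed alternative would remove any SNP
monomorphic in a small breed, which is exactly the signal a selection scan
needs. Relatedness is assessed within each breed with a method-of-moments
IBD estimator in the PLINK `--genome` style: observed identity-by-state
counts across SNPs are equated to their expectations given the IBD state
(0/1/2 shared alleles), using without-replacement allele products so the
expectations stay unbiased when frequencies come from the same small
sample. z0, z1, z2 are solved sequentially, clamped to [0, 1] and
renormalized; PI-HAT = z2 + z1/2. SNPs with within-breed MAF < 0.01 are
excluded from the estimator (near-monomorphic sites make the IBS0
expectation ≈ 0 and the moment solution degenerate). Pairs with PI-HAT
> 0.3 are pruned greedily: repeatedly drop the sample involved in the most
violating pairs, preferring higher missingness then the smaller id — on a
chain A–B–C this removes only the hub, giving a minimal set under the
rule. The QC cascade is SNP filters → sample filter → IBD pruning → MAF
re-filter, so frequencies remain valid after sample removal; every filter
is idempotent.

## Polarization

The ancestral allele is taken from a provided table when available,
otherwise as the strict majority allele among non-missing outgroup calls.
An exact 50/50 outgroup split (or zero calls) leaves the SNP unresolved and
excluded from the scans: any arbitrary tie-break would flip the sign of
ΔDAF at that SNP, which is worse than losing it. Outgroup samples are
excluded from all breed-level frequencies. A breed with zero calls at a
SNP has *undefined* DAF (NaN), never 0 — downstream averages and filters
skip undefined entries instead of biasing toward the ancestral state.

## Selection scan

F_ST is the Weir–Cockerham (1984) two-population θ from the variance
components a (between populations), b (between individuals within
populations) and c (within individuals), computed from genotype counts
with observed heterozygote frequencies. Negative estimates are kept as-is
(they are informative of "less than none" differentiation and averaging
over pairs relies on them); θ is undefined — not 0 — when both breeds are
monomorphic for the same allele, and such pairs are excluded from the
breed-pair average. Counting them as 0 would asymmetrically deflate loci
that have drifted to fixation in both groups.

ΔDAF is ranked signed, not absolute: the scan targets derived alleles
risen specifically in fat-tailed breeds, and the wild ancestor is
thin-tailed, so sweeps in the thin group are deliberately out of scope.

The top-1% cutoff is the value at rank ⌈q·N⌉ from the top among defined
values; every SNP at or above the cutoff is flagged, ties included —
truncating at the rank would make results depend on sort stability. A SNP
is positively selected in a comparison when both statistics flag it, and a
consensus candidate when selected in *every* comparison. The worldwide
consistency filter then removes SNPs with DAF > 0.5 in more than
⌊0.30·n_thin⌋ thin breeds or DAF < 0.5 in more than ⌊0.30·n_fat⌋ fat
breeds; with the default 18/14 breed panel these integers are 5 and 4.
Breeds with undefined DAF at a SNP are excluded from both the count and
the group total. Gene annotation reports every gene whose interval
overlaps [pos − 150 kb, pos + 150 kb], both endpoints inclusive.

## Population structure

LD pruning is greedy within sliding windows (defaults 50 SNPs, step 5,
r² > 0.2, PLINK-conventional): while any retained pair in a window exceeds
the threshold, the lower-MAF member is dropped (tie → later position).
PCA standardizes genotypes GCTA-style (center 2p̂, scale √(2p̂(1−p̂)),
mean-imputed missing) and takes left singular vectors. The outlier rule —
flag a sample farther than 3 robust SDs (1.4826·MAD) from its own breed's
centroid on any retained component — makes "outside its expected cluster"
reproducible; with small breeds the MAD is noisy and the rule
over-flags somewhat, so the flags are advisory output, not an automatic
filter. The breed tree applies canonical neighbor-joining (scikit-bio) to
Nei's standard genetic distance D = −ln(J_xy / √(J_x·J_y)) computed from
per-breed allele frequencies over loci defined in both breeds; negative
branch lengths are clamped to 0.

## Region analysis

Group |ΔAF| pools all fat and all thin samples. Elevated regions are the
package's reproducible operationalization of "visibly elevated" stretches:
variants with |ΔAF| above the threshold (default 0.6) join a cluster while
consecutive hits are ≤ 5,000 bp apart, and clusters with ≥ 5 members
become regions spanning [min pos, max pos] (length end − start + 1). The
haplotype matrix over a region includes *all* polymorphic variants in the
span, not only the above-threshold ones, two rows per sample, fat group
first, columns in position order; unphased input raises an error unless
the explicit genotype-dosage fallback is requested. High-confidence
candidates require |ΔAF| > 0.8 and fat-group derived-allele frequency
> 0.8, both strict; variants without an ancestral assignment are excluded
and logged.

## Synthetic data

The generator draws per-breed derived-allele frequencies from the
Balding–Nichols model: Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
frequency p ~ Uniform(0.05, 0.95), genotypes Binomial(2, p_breed). Planted
selected loci instead center fat breeds at 0.9 and thin breeds at 0.1
(Beta, concentration 20), emulating a derived allele near fixation only in
the fat-tailed group. Defaults mirror the study design the scan targets:
18 thin-tailed breeds (5 South-Asian, 6 European, 3 American, 4 Nepalese),
14 fat-tailed (6 Middle-Eastern, 4 African, 4 Chinese), 25 samples per
breed, 8 outgroup individuals, drift F = 0.1 (typical for livestock breed
divergence), 2% missingness; the three default comparisons contrast
Middle-East fat vs South-Asian thin (6×5 breeds), Middle-East fat vs
European thin (6×6) and Chinese fat vs South-Asian thin (4×5). The
outgroup is drawn at derived frequency min(p, 0.05) rather than fixed
ancestral, so polarization's tie/unresolved paths are exercised. Related
pairs replace a breed member with a gamete-dropped child of another
member. Regional haplotypes place two backgrounds differing at all block
sites; fat haplotypes carry the alternative background with probability
0.9, thin with 0.1, non-block sites are i.i.d. at shared frequencies, and
every emitted site is polymorphic (it represents a discovered variant).
Because all block sites share one background assignment, their realized
|ΔAF| is identical (≈ 0.8) — real data would show per-site variation on
top of this.

What the generator does *not* emulate: linkage disequilibrium among array
SNPs (the scan is per-SNP, so frequency-level simulation reproduces
exactly the statistics it consumes), demographic history, genotyping
error, and ascertainment bias of array content. Passing tests therefore
demonstrate correctness of the statistical machinery and its operating
characteristics under the assumed drift model, not performance on real
array data with LD structure.

## Problem sizes and determinism

The acceptance run simulates 20,000 neutral + 20 planted SNPs with 25
samples per breed (808 individuals), the scale at which the scan's
operating characteristics (≥ 90% planted recovery, ≤ 1% neutral consensus
rate) are measured; the estimator oracle uses 200 random two-breed
configurations, structure checks 100 samples × 2,000 SNPs at F = 0.2, and
the determinism check reruns the full pipeline at 3,000 SNPs. Every source
of randomness flows from a single integer seed through
`numpy.random.default_rng`; sorts are stable and iteration orders fixed,
so identical seed + config reproduce byte-identical outputs.

## Known limitations

- Only biallelic SNPs are supported; multi-allelic records and indels are
  dropped at VCF ingestion.
- No assembly liftover: all inputs must share one coordinate system.
- The percentile null is empirical; no simulation-based significance is
  attached to scan hits or regions.
- The PCA outlier flag over-reports for breeds with very few samples (MAD
  degeneracy); inspect before excluding samples.
- Phasing is taken from the input VCF; the package does not phase.
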