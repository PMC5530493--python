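# Methods

`chipdesign` implements the computational pipeline used to design dense SNP
genotyping arrays from whole-genome-sequence variant catalogs, in the style
of the MNEc2M / MNEc670k equine arrays: consensus variant catalog → quality
recalibration → array-compatibility filtering and LD pruning → windowed
quota selection of a high-density design set → tag-SNP set cover within and
across populations → a final labeled commercial-array list → mask-and-impute
validation.  This note records the models, the defaults and why, and the
choices made where the procedure was genuinely open.

## Variant catalog and coordinates

The catalog holds bi-allelic SNVs only; multi-allelic records and indels are
skipped at read time (array probes target single-base substitutions).
Positions are 1-based (VCF convention) everywhere user-visible; genomic
windows use half-open 0-based intervals internally, so a 1-based position
`pos` lies in the window containing `pos − 1`.  Two-caller consensus is an
intersection on `(chrom, pos, ref, alt)`; the first catalog is the primary
caller and supplies QUAL and annotations for the surviving sites.  Sites
agreeing on the locus but not the alternative allele are excluded and
counted, not silently dropped.

Missing annotations are tracked explicitly as missing. The two rank-sum
statistics (MQRankSum, ReadPosRankSum) are legitimately absent at sites with
no heterozygous carrier, and zero is a meaningful rank-sum value, so missing
is never imputed to zero.

## Quality recalibration (VQSLOD)

The recalibration model is a two-class Gaussian density ratio over the five
standardized annotations (DP, QD, FS, MQRankSum, ReadPosRankSum):

- **positive class**: multivariate Gaussian fit to a trusted ("gold
  standard") subset — legacy-array overlap, recurrence in ≥ k calling
  groups (default k = 4), or the top percentile of QUAL (default 1%);
- **negative class**: Gaussian fit to the fraction of sites least plausible
  under the positive model (lowest-density tail, default 5%);
- **score**: `VQSLOD = log10 p₊(x) / p₋(x)`, clipped to ±20.

This is the density-ratio contract of variant-quality recalibration reduced
to its fully specifiable core; the adaptive mixture-count machinery of
production recalibrators is deliberately out of scope.  A regularized
logistic-regression backend (gold vs rest) is provided as an alternative
ranking model.

Numerical choices: annotations are standardized per feature, which makes
scores invariant under affine rescaling of any single annotation;
covariances get diagonal loading of 10⁻⁶ × trace to guarantee positive
definiteness; zero-variance annotations are dropped with a warning; sites
with missing annotations are scored on the marginal Gaussian over their
observed dimensions.  Training chromosomes are a parameter (default: all
supplied chromosomes) so evaluation can be held strictly
out-of-chromosome; the model records the set it was trained on.

## Cross-platform concordance

Concordance is pooled over genotype cells (site × sample), not averaged per
site, matching the "cumulative proportion of genotypes" convention.  Calls
missing on either platform leave both numerator and denominator.  Dosage
comparison makes phase irrelevant.  Precision curves rank sites by
decreasing score with ties broken by genomic position, so curves are
reproducible; the final point of a curve depends only on the comparison set,
never on the ranking.

## Array-compatibility filters

- **Repeats**: position inside any repeat-mask interval (BED half-open).
- **Proximity**: another variant within 20 bp (center-to-center, both
  members of a close pair removed).  Proximity is evaluated against the
  full consensus catalog, not the post-filter survivors: probe interference
  comes from any real polymorphism in the flank, including ones rejected
  for other reasons.
- **Rarity**: fewer than 2 observed minor-allele copies.  At the cohort
  sizes these arrays are designed from, this is the same rule as a "MAF
  below 1%" cutoff.
- **Fixed non-reference**: alternative-allele frequency exactly 1.0 among
  non-missing calls; such sites are reference-assembly error candidates and
  unusable as array content.

The three marginal content filters commute; their per-filter counts overlap,
so the report tracks per-filter and unique-site removals separately (the
published removal counts are likewise non-additive).

**LD pruning** scans each chromosome left to right.  For any surviving pair
within 10 kb with r² > 0.90, the member observed in more priority calling
groups (historically draft and pony, which earlier arrays under-served) is
kept; ties keep the higher VQSLOD, then the left site.  The loser is removed
immediately and takes no further part, which guarantees — verified against a
brute-force pair enumeration in the tests — that no surviving pair within
the window exceeds the threshold.  The scan order is a design choice (the
published procedure does not state one); deterministic left-to-right was
chosen for reproducibility.

## Windowed quota selection

The genome is tiled into 50 kb windows (≈54,000 for a 2.7 Gb genome) with a
37-SNP target per window, filled greedily by tier: (1) legacy-array VIP,
(2) Mendelian-trait VIP, (3) 'recommended' single-probe, (4) 'neutral'
single-probe, (5) MHC-region, (6) two-probe (A/T, C/G alleles).  VIP and
MHC sites are always included, even above quota; otherwise they count
against it.  Within a tier, ties break by VQSLOD descending then position —
consistent with VQSLOD tie-breaking elsewhere in the pipeline.  Two open
points resolved here: single-probe 'not recommended' sites, which the
six-tier list does not place, get a fallback tier 7 used only when a window
is under quota; and a VIP SNP's two strand probes count as one site against
the quota.  Strand choice takes the better recommendation class; equal
classes take the forward strand.

## Tag-SNP selection and array assembly

Within one sample set, tagging is greedy set cover: a site covers itself
and every site whose squared dosage correlation reaches the threshold
(inter-population pass: MAF ≥ 0.01, r² ≥ 0.99; per-breed pass: MAF ≥ 0.10,
r² ≥ 0.90); the site covering the most uncovered targets is taken
repeatedly.  Greedy cover is within the classical (1 + ln n) factor of
optimal, which the tests confirm against exhaustive minimal covers on small
panels.  Two-marker rules (optional, `max_markers=2`) let a pair of
already-selected tags cover a target through the R² of a joint linear
regression — the multi-marker generalization, capped at order 2.  r² is
computed from genotype dosages by default; phased-haplotype r² is available
when phase is present.

Across populations, a near-minimal spanning set is built greedily: pick the
SNP admissible as a tag in the most populations still needing coverage,
rebuild the remaining requirements, repeat.  Every population's coverage
contract is preserved by construction.

The final array is assembled by six inclusion criteria in precedence order
— Inter, Intra (tag in ≥5 breed groups), Diverse (tag in ≥3 of the four
designated high-diversity groups), MHC, Density (fill each 50 kb window to
≥8 SNPs, highest VQSLOD first), VIP — each SNP carrying the first label
that admitted it, so label counts sum exactly to the array size.  "Tag in a
breed group" means membership in that group's tag set after per-population
tagging, before the spanning pass (configurable).  The density-fill ranking
(VQSLOD then position) is a design choice; the published procedure does not
state one.

## Mask-and-impute validation

One third of each breed group (rounded, minimum 1; groups under 3 samples
warn) is held out, masked down to the low-density site set, and imputed
from the remaining individuals.  Held-out samples are removed from the
reference panel before imputation — asserted structurally, not by
convention.

The built-in imputer is a diploid Li-Stephens haplotype-copying model: the
target's two haplotypes are mosaics of the K reference haplotypes with a
uniform per-site template-switch probability (default 0.01) and a genotype
mismatch probability (default 0.01).  Because the transition kernel
factorizes per haplotype, forward–backward over ordered haplotype pairs
costs O(K²) per site rather than O(K⁴).  Masked sites contribute flat
emissions; their posterior dosage distribution yields both a best-guess
genotype (maximum posterior) and an expected dose.  Unphased reference
panels are pseudo-phased deterministically (seeded random het splitting) —
adequate for the strong-LD regimes the harness simulates, and noted as a
simplification.  An external imputer can be plugged in at the VCF level in
place of the built-in model.

Accuracy is reported as per-individual concordance over masked sites
(phase-insensitive, missing excluded), per-group mean ± s.e.m. (n =
held-out individuals), and Pearson correlation of imputed vs true
minor-allele dose within bins of reference-panel minor allele count.
Constant-dose bins have undefined correlation and are reported as NaN.

## Probe QC

Conversion categories are a pure function of one probe's calls: call rate
below threshold → `CallRateBelowThreshold`; bad clustering → `Other` (the
caller supplies the cluster flag; the vendor's twelve underlying cluster
metrics need raw intensities and are out of scope, as is DishQC); fewer
than two samples carrying the minor allele → `MonoHighResolution`; minor
carriers but no minor homozygote → `NoMinorHom`; otherwise
`PolyHighResolution`.  Best-probe selection follows that quality order with
one guard: a `NoMinorHom` probe with Hardy–Weinberg χ² p ≤ 10⁻⁵ (1 df,
expectations from sample allele frequencies; monomorphic → χ² = 0, p = 1)
is ineligible.  Sample QC is two-stage: individual call rate ≥ 0.97, then
plate pass rate ≥ 95% (blood) or ≥ 93% (hair).

## Synthetic cohorts

The simulator produces everything the pipeline consumes.  Haplotypes are
mosaic copies: a few deep founder haplotypes carry the allele-frequency
spectrum (Beta(0.8, 2.2) site frequencies); the base pool of 24 haplotypes
is built from founder mosaics (ancestral block scale 2 × 10⁻⁶ /bp switch,
1% private mutation), and each sample haplotype re-mosaics a breed-specific
pool subsample with a distance-dependent switch probability
(1 − e^(−ρ·d), default ρ = 10⁻⁶ /bp).  This yields block LD that decays
with distance and with ρ, and breed differentiation that grows with the
drift parameter (default 0.3 = each breed draws 70% of the pool).  The
default cohort is 8 breeds × 8 diploids on two 1 Mb chromosomes with 2000
sites — deliberately desk-scale while preserving the qualitative structure
(multi-breed, blocky LD, unbalanced frequency spectrum) the pipeline's
behaviour depends on.

Artifactual sites (default 5%) carry no haplotype structure (iid rare
alleles) and draw their annotations from shifted distributions (lower QD,
higher FS, displaced rank sums); QUAL is log-normal with a small class
shift, so QUAL ranks the classes imperfectly while the annotations separate
them well — the regime in which recalibration demonstrably helps.  Array
assay noise flips each call to another dosage with probability 0.005 and
hides it with probability 0.02, matching the high cross-platform
concordance regimes observed on real arrays.

What the simulator does **not** emulate: read-level data (no FASTQ/BAM),
coalescent genealogies, recombination hotspots, genotyping batch and
intensity effects, and realistic site densities (thousands of sites, not
millions).  Passing tests therefore demonstrate correctness of the
selection logic and qualitative reproduction of the method's behaviour
(score-ranking dominance, two-regime imputation, frequency-dependent
imputation accuracy), not quantitative agreement with any real cohort.

## Problem sizes

Test and acceptance runs use cohorts of 150–2,500 sites and 10–60 samples,
reference panels of up to 60 haplotypes, and exhaustive oracles on panels
of ≤ 15 sites (set cover) and ≤ 50 sites (LD pruning) — sizes at which the
brute-force references are exact and the full pipeline remains interactive.

## Known limitations

- The Gaussian pair is a deliberate simplification of adaptive-mixture
  recalibration; heavy-tailed annotation distributions would be better
  served by more components.
- Greedy tag cover and greedy spanning are near-minimal, not minimal.
- The diploid copying model assumes a uniform switch rate (no genetic map)
  and uniform copying probabilities (no mutation-rate or frequency
  weighting).
- Published cohort-level results (breed imputation accuracies, inter-SNP
  distance tables, LD decay curves) require the original genotype data and
  are reproduced only as arithmetic identities or qualitative properties.
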