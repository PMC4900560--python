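# Methods

`sweepscan` detects and characterizes recent positive selection in a
focal population from phased haplotypes of three labelled populations
(focal, background, outgroup).  This note documents the statistical
model behind each stage, the tunable parameters, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Differentiation statistics

**Per-SNP F_ST.**  Phased haplotypes are treated as sampled alleles
(haploid samples).  For two populations with allele counts
(c₁, n₁), (c₂, n₂) per site, the Weir–Cockerham (1984) variance
components reduce to a between-population component *a* and a
within-population component *b*; the per-site estimate is θ̂ = a/(a+b).
An alternative reading — computing per-SNP F_ST from diploid genotypes
with heterozygosity terms — would require genotype-level data the panel
abstraction deliberately drops; with fully phased data the haploid
treatment is both standard and strictly more informative.  Both
monomorphic-and-identical sites give 0/0 and are reported NaN with a
flag.  Negative estimates (expected for ~half of all sites under
neutrality) are reported as-is and also *ranked* as-is in the composite
score: flooring them at zero would tie roughly half the genome at one
rank and visibly distort the null distribution of the combined score.

**Windowed Reynolds F_ST.**  The Reynolds, Weir & Cockerham (1983)
coancestry estimator shares the same per-site components; windows use
the ratio-of-sums Σa / Σ(a+b) over the sites of each non-overlapping
tile (1 kb and 100 kb, fixed origin at position 0, half-open).
Ratio-of-sums is stable in low-diversity windows where a mean of
per-site ratios would be dominated by near-0/0 sites.  A single-site
window therefore equals that site's per-site value.

**Divergence times and PBS.**  Window F_ST is transformed to
T = −ln(1 − F_ST); window values are clamped to [0, 1−10⁻⁶] first so T
stays finite (the clamp bounds come into play only for empty-variance or
fully fixed windows).  With 1 = focal, 2 = background, 3 = outgroup,

    PBS = (T12 + T13 − T23) / 2,

positive when the focal branch is long, i.e. divergence specific to the
focal population.  Every SNP inherits the PBS of its containing 1 kb
window ("local PBS").

## Haplotype homozygosity

**EHH.**  For a core SNP and a boundary site, haplotypes are grouped by
exact allele-string identity over the closed site interval;
EHH = Σ_g C(n_g,2) / C(n,2).  At zero extension the groups are the two
core allele classes.  The whole-sample (not allele-partitioned) form is
used, as the cross-population contrast requires.

**iHH and XP-EHH.**  iHH is the trapezoid integral of the EHH decay
curve over genetic distance (cM), per flank, summed.  Integration stops
at the first site below the EHH cutoff (default 0.05), adding a partial
trapezoid to the linearly interpolated crossing.  Two data-quality
rules, applied per flank and per population: a physical gap
> 10,000 bp to the next variable site reached while EHH is still at or
above the cutoff flags the core as gap-discarded (a hit in *either*
population discards the core — the conservative reading); reaching the
chromosome's last variable site first truncates the integral there and
sets a separate edge flag (edge cores are retained — both populations
truncate at the same place, so the log-ratio is still meaningful, and
discarding them would hollow out short test chromosomes).

    XP-EHH raw = ln(iHH_focal / iHH_background)

per core SNP with minor allele frequency ≥ 0.02 in the joint
focal+background sample (a per-population MAF switch is exposed).
Scores are normalized genome-wide, (raw − mean)/sd over retained cores;
normalization is refused (raw only) below 50 retained cores.  Positive
values mark long haplotypes — recent sweeps — in the focal population.

## Composite Selection Score

All SNPs carrying both statistics are ranked for F_ST and for normalized
XP-EHH; fractional ranks r = (rank − 0.5)/n (average ranks for ties) are
mapped to normal quantiles z = Φ⁻¹(r) and averaged: z̄ = (z_F + z_X)/2.
CSS = −log₁₀ p with p the upper-tail normal probability of z̄.  Two
standardisations are exposed:

* `literal` (default): p = 1 − Φ(z̄).  This reads z̄ against a standard
  normal and reproduces the conventional score scale (top SNPs ≈ 3–5).
* `exact`: p = 1 − Φ(z̄·√2), the exact null of a mean of two independent
  standard normals.  Under neutral input the exact-mode z̄·√2 is
  standard normal (verified by KS test).

The two modes are monotone transforms of each other, so rankings,
percentiles and candidate sets are identical; only the score scale
differs.  CSS is invariant to any strictly monotone transform of either
input statistic.  The upper tail is one-sided by construction: jointly
high F_ST and XP-EHH → high CSS.  Window-level CSS ranks windowed
Reynolds F_ST and windowed mean XP-EHH the same way; gene-level CSS is
the mean CSS of 1 kb windows overlapping the gene body ± 2 kb.

## Candidate selection

Top-N (default 1000) SNPs by CSS among those within 8,000 bp of a gene
body (distance to the body interval, strand ignored, 0 if inside; ties
broken by F_ST then position).  Candidate genes are those with at least
one linked top SNP at F_ST > 0.8.  Candidate genes are clustered into
putative sweeps by single linkage over their linked outlier SNPs
(merge distance default 50 kb, exposed — chosen to match the observed
scale at which linked differentiation decays to background around the
strongest outliers).  Feature-class enrichment of top SNPs uses
fold = (b/n)/(B/N) with a two-sided Fisher exact test on the 2×2 table;
one class per SNP with CDS > UTR > intron > intergenic precedence.
Binned-mean profiles (mean PBS or XP-EHH per F_ST bin of 0.05, bins with
≥ 10 SNPs) and linked-signal decay profiles (windowed statistic versus
distance from anchor SNPs, two sides averaged per offset, one-sided at
edges) carry 95% percentile-bootstrap CIs from 200 seed-controlled
replicates resampling SNPs (respectively anchors).

## Sweep characterization

The core SNP of a region is the highest-F_ST SNP, ties broken by
XP-EHH, then leftmost.  Focal haplotypes carrying the focal-major allele
at the core are "selected"; remaining focal plus all background
haplotypes are "unselected" (an exact 50/50 focal split is an error —
there is no major allele to pick silently).  π is the mean pairwise
count of differing sites per window (the per-window sum; per-bp
normalization cancels in the ratio below, which is verified by a test).

    Δπ = (π_selected − π_unselected) / π_unselected

is traced in non-overlapping windows laid out from the core: 0.01 cM
windows to 20 cM per side (genetic mode) or 1 kb windows to 2 Mb per
side (physical mode).  Window 0 is centred on the core (it contains the
core variant); window k covers distances ((k−½)w, (k+½)w].  The profile
is folded: at each k, π is averaged over the up- and downstream windows
per group before forming Δπ (one-sided at chromosome edges).  The
background level Δπ_B is the mean Δπ over each profile's 1000 most
distant defined windows, pooled across sweeps and computed per mode
(the genetic- and physical-mode backgrounds are kept separate).  Sweep
length is the distance from the core to the midpoint between the first
recovered window (Δπ ≥ Δπ_B) and its predecessor — (k + ½)·w — giving
half-window (0.005 cM) resolution; the bp extent is the inverse-map
image of that genetic distance on each unfolded side, rounded to 1 kb.
A profile that never recovers is called at the scan range and flagged,
as is degenerate recovery at the core window itself.  A sweep is "hard"
when the selected haplotypes carry zero diversity over the ±0.01 cM core
region and "soft" otherwise; the core-region Δπ is reported in percent.

## Synthetic data

The generator produces a three-population phased panel with known
ground truth, emulating the study conditions the scan is designed for:
10 / 20 / 28 diploid individuals (focal / background / outgroup), SNP
density 1/30 bp (Poisson positions), a uniform 25 cM/Mb map in 100 kb
rate windows, and drift calibrated so the focal–background genome-wide
F_ST is ≈ 0.044.

*Frequencies.*  Ancestral p ~ Uniform(0.05, 0.95) per site; each
population draws q from the Balding–Nichols Beta,
q ~ Beta(p(1−φ)/φ, (1−p)(1−φ)/φ), so Var(q) = φ·p(1−p) and the expected
pairwise F_ST between two populations of dispersion φ is ≈ φ.  Defaults:
φ_focal = φ_background = 0.044; φ_outgroup = 0.20 (a more diverged
outgroup, giving mean windowed PBS of a few hundredths under
neutrality).

*Haplotypes.*  Each population holds a pool of F = 10 founder
haplotypes whose per-site allele counts are matched to round(F·q) — a
Bernoulli pool would add Var ≈ q(1−q)/F of spurious drift and inflate
F_ST well above its configured value.  Each sampled haplotype is a
Markov mosaic over the pool: the probability that a *pair* of haplotypes
keeps a shared founder decays as exp(−d/λ) in genetic distance, with
λ = `ld_decay_cm` = 0.02 cM (≈ 800 bp at 25 cM/Mb) by default.  This
matches the empirically very short neutral LD of a genome recombining at
25 cM/Mb; it is deliberately an order of magnitude shorter than sweep
footprints, which is what makes planted sweeps stand out of the neutral
EHH background, and it is exposed as a parameter.  Founder sharing gives
both LD that decays with cM distance and EHH curves that fall from
Σp² ≈ 0.5 at the core through a ≈ 1/F plateau to below the 0.05 cutoff
within a few hundredths of a cM.

*Sweeps.*  A planted sweep raises the count of carriers of allele 1 at
the core site to round(f·2n_focal) exactly (f = `selected_freq_focal`);
carriers copy one of k template haplotypes (k = 1 hard, k > 1 soft) over
a flank whose half-width is Exponential(`footprint_cm`, default 0.1 cM)
per carrier per flank, but never less than the ±0.01 cM core haplotype
region — so a k = 1 sweep is a single core haplotype by construction,
while the per-carrier exponential extents make Δπ recover gradually at
the footprint scale, as recombination would.  The selected allele is
planted rare outside the focal population (`freq_background`, default
0.05, matching the ~1–2% typical of strongly selected focal variants in
a background population).  Cores whose footprints collide raise an
error.  Everything is driven by one RNG stream keyed by (seed,
chromosome); identical configs give byte-identical VCF output.

*What the generator does not emulate:* coalescent genealogies and their
long-range correlation structure, mutation-rate heterogeneity, site
frequency spectra under demography, missing or unphased genotypes, and
selection acting through time (sweeps are painted on, not evolved).
Passing tests therefore demonstrate that the estimators and the
candidate/sweep machinery behave correctly on panels with realistic
frequency differentiation and cM-scaled haplotype sharing — not that the
pipeline's power on real data equals its power here.

## Numerical choices and conventions

* Coordinates 0-based half-open internally; VCF/GFF3 1-based at I/O.
* Windows are fixed-origin non-overlapping tiles from position 0.
* NaN never appears in output files: empty cell plus a `*_defined` flag.
* Statistics are allele-label symmetric except sweep partitioning, which
  uses the focal-major allele; no ancestral-allele inference anywhere.
* Sites with any missing genotype are dropped at VCF load.
* Genetic-map transforms are piecewise linear per rate window and
  invertible to within 1 bp.
* EHH haplotype identity is exact string equality, no mismatch
  tolerance; ties in ranking get average ranks everywhere.
* Bootstrap CIs are percentile-method, seed-controlled.

## Problem sizes

The test suite and the acceptance script run the scan at desk scale,
chosen so the whole suite completes in well under an hour on one CPU:
neutral calibration on five 1 Mb chromosomes (~33,000 SNPs each);
sweep-recovery on 100 replicates of a 400 kb chromosome (~13,000 SNPs)
with one planted hard sweep at focal frequency 0.95 and footprint
0.1 cM; estimator-oracle checks on 200 random panels of up to 40
haplotypes × 50 sites.  All per-bp densities, rates, sample sizes and
thresholds are the study conditions above — only chromosome length is
scaled down.

## Known limitations

* The XP-EHH contract mirrors the conventional implementation
  (trapezoid iHH in cM, 0.05 cutoff, gap discards) but is an independent
  implementation; per-SNP values are not expected to be bit-identical to
  other tools, and the discard bookkeeping near scaffold borders can
  differ at the margin.
* Sweep grouping by single linkage at a fixed merge distance is an
  explicit, exposed approximation of what is ultimately a manual
  curation step.
* Gene-level CSS weights every overlapping window equally regardless of
  overlap fraction.
* The pipeline operates per chromosome; multi-chromosome inputs are
  scanned chromosome by chromosome and normalization is per-run.
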