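# Methods

This note documents the statistical model the package implements, the
assumptions and defaults of its synthetic-data generator, the numerical
choices that were genuinely open, and what the test suite does and does not
demonstrate about real field data.

## The experimental design

The package analyses a replicated whole-river BACI experiment: in each of
six rivers, one upstream **reference** site (intact riparian vegetation,
the source of drifting detritus and of potential colonists) and six
downstream experiment sites at ~1 km spacing, three **control** and three
**manipulation**, allocated at random within consecutive upstream / middle /
downstream pairs. All sites are sampled **before** and **after** channel
retentiveness is increased at the manipulation sites. Responses are detritus
standing stock (g m⁻² from 15 pooled 0.30 × 0.33 m² Surber samples), taxon
richness, total macroinvertebrate density, per-taxon densities, and
community composition.

## Univariate model and inference

`fit_baci_anova` fits the balanced three-factor repeated-measures
decomposition: Treatment (fixed, 2 levels) × River (fixed, 6) × Time
(repeated, 2), with Site nested in Treatment × River. Sums of squares come
from the classical marginal-means identities for balanced designs and are
checked in the tests against an independent projection (hat-matrix) oracle.
Reference sites never enter this model; they are used only as equivalence
targets.

Two error strata determine every F ratio: Treatment, River and
Treatment × River are tested over the Between-sites (within
Treatment × River) mean square; Time and all Time interactions over the
Residual (Time × Site) mean square. The mapping is fixed by the internal
consistency of the motivating study's published tables (e.g. 98 901/11 500 =
8.60 and 175 143/11 378 = 15.39); one printed Time cell in those tables is
arithmetically inconsistent with any fixed mapping and is treated as a
typesetting artefact. `reconstruct_f` exposes the mapping so the printed
ratios can be regenerated from mean squares alone.

**Transform.** "Log where necessary" is operationalised as log10(x+1),
triggered when the max/min ratio of the River × Treatment × Period cell
variances exceeds 4 (configurable, with `'none'`/`'log'` overrides). With
three sites per cell the variance estimates are noisy and the rule triggers
for most skewed data, which matches how routinely such data are
log-analysed in practice.

**A priori contrast.** The treatment contrast is
L = x̄_BC + x̄_BM + x̄_AC − 3 x̄_AM with
F = L²/(MS_res · Σc²/n_cell), Σc² = 12, on 1 and the residual df. P is the
ordinary (two-sided) F tail; the sign of L carries the direction. Per-river
contrasts reuse the pooled Residual MS with n_cell = sites per cell; the
river with the smallest |ES| is left untested to keep the remaining
contrasts independent, ties breaking alphabetically (logged).

A caveat worth knowing: the coefficients (1, 1, 1, −3) do not cancel
site-level random effects (control sites enter +2/n, manipulation sites
−2/n), so with strong persistent site effects in a response the
residual-MS-based contrast is anticonservative. The generator's default
responses keep persistent site effects small relative to observation noise
(see below), where the test is essentially exact — verified by the null
calibration test (rejection rate 0.046 at α = 0.05 over 1000 null
replicates).

**Effect size.** ES = 100 (x̄_AM − Y)/Y, Y = (x̄_BC + x̄_BM + x̄_AC)/3,
reported on the data scale: when the model ran on log10(x+1) data the cell
means are back-transformed (geometric-type means) first, so ES stays a
percentage of raw densities. Being a ratio, the estimator carries a small
O(1/n) positive bias (≪ 1% at the default design size); the recovery test
therefore checks that the central 95% Monte-Carlo interval of the ES
estimates covers the generating value, not that the mean is exactly
unbiased.

**Responder classification.** A taxon is "common" in a river when its total
count (all sites, reference included — new colonists live only at the
reference before treatment) is ≥ 20 and it occupies ≥ 4 site × period
cells; both thresholds are arguments. Counts are always analysed
log10(x+1) (per-taxon counts are the archetypal case where the variance
rule fires). Each common taxon gets each river's a priori contrast;
significant taxa are classed by presence pattern at the manipulation sites
(new: absent before, present after; lost: the reverse) and otherwise by the
sign of ES.

**Tukey letters.** `one_way_anova_tukey` wraps the studentised-range test
(scipy) and produces a compact letter display by insert-and-absorb, so
groups that are not significantly different share a letter.

## Bio-equivalence

R = mean(manipulation, after)/mean(reference targets), the target being the
arithmetic mean of the six per-river reference-site values (reference sites
are unreplicated within rivers, so the target's sampling variance is taken
across rivers, df = 5). The CI construction is not specified in the
motivating work; Fieller's interval for a ratio of independent normal means
is used (exact under normality), with a seeded percentile bootstrap built
in as a cross-check (they agree within 0.05 on well-behaved fixtures). The
90% two-sided interval corresponds to the one-tailed α = 0.05 test of
R ≤ R_l: equivalence is declared exactly when ci_low > R_l (= 0.8 by
default), and the interval is also reported against 1.0 ("full
equivalence"). When the reference mean is not significantly positive
(Fieller g ≥ 1) the interval is unbounded and the result is flagged, never
silently truncated.

For composition, the ratio of mean Bray–Curtis similarity
(manipulation → reference, after) to mean similarity among controls (after)
is tested one-tailed against ≤ 1 by a seeded bootstrap over the two
similarity sets. The inference method here is wholly an implementation
choice: similarities within a river share sites and are not independent, so
the bootstrap P is approximate and is labelled as such in the output.

## Community analyses

Abundances are 4th-root transformed and converted to Bray–Curtis
dissimilarities on the 0–100 scale (all-zero sample pairs are undefined:
NaN plus a warning, and they are rejected by downstream analyses rather
than imputed). PERMANOVA partitions the Gower-centred matrix
G = −½ J D² J by the balanced design's orthogonal projectors; on Euclidean
distances of a univariate response this reproduces the classical ANOVA
term-by-term (the McArdle–Anderson identity), which the tests assert to
1e-6 on random fixtures — this is the module's primary correctness anchor.
Pseudo-F uses the same denominator mapping as the univariate table.

**Permutation strategy** (the design's restricted scheme is not described
in the motivating work, so it is declared here and recorded per source row
in the output):

* Treatment and Time × Treatment: permute whole sites **within rivers** on
  the raw matrix. Each river keeps three sites per arm, so river and
  river-time effects cancel in the permuted statistic; under the term's
  null the site units are exchangeable and the test is essentially exact.
* River and Time × River: permute whole sites within treatment arms.
* River × Treatment and the three-way interaction: no clean stratum exists;
  Freedman–Lane permutation of reduced-model residuals with free site
  permutation.
* Time: within-site period swaps of reduced-model residuals.

An earlier variant that swapped period labels for all within-subject terms
was measurably conservative for Time × Treatment (the within-site *change*
is a per-site quantity, so sites — not period labels — are the exchangeable
units); the shipped scheme passes a KS uniformity check of P(perm) on null
data. Pairwise two-group tests report t = √pseudo-F with freely permuted
group labels.

**NMDS** minimises Kruskal stress-1 by SMACOF majorization with isotonic
regression of configuration distances on the input dissimilarities
(disparities rescaled to the distances' norm each iteration, which prevents
the configuration from shrinking into a spurious collapse); 20 seeded
random restarts by default, tolerance 1e-6, max 500 iterations, best
restart returned centred and rotated to principal axes, with the stress
trajectory kept (majorization makes it non-increasing). When the
dissimilarities are rank-separable into tight clusters — as happens for
strongly treated synthetic communities, where manipulation-after samples
split cleanly from the rest — a two-clump configuration is a genuine
zero-stress optimum; near-zero stress on ≥10 samples triggers a
degeneracy warning rather than being reported as a good fit. **SIMPER** averages
each taxon's share of the Bray–Curtis numerator over all between-group
pairs; the contributions sum exactly to the average between-group
dissimilarity. Centroid trajectories report before→after displacement per
river × treatment group; displacement lengths are rotation-invariant.

## The synthetic-data generator

The generator emulates the experiment's statistical structure, not stream
ecology. Counts are gamma-Poisson (negative-binomial-type; `dispersion` is
the gamma shape k, Var = μ + μ²/k, k → ∞ giving Poisson) around log-scale
means composed of a per-taxon baseline (lognormal across taxa, median
`baseline_abundance` = 30 per pooled site sample, spread `taxon_sd` = 1)
plus river (sd 0.4), site (sd 0.2) and period (sd 0.15) effects. All three
effects are **taxon-specific and independent across taxa**: a site that is
good for one taxon says nothing about another. That choice makes aggregate
responses (richness, total density) average the effects away, keeping the
(1, 1, 1, −3) contrast calibrated for them, and is defensible at the
microhabitat scale, but real sites share productivity gradients that would
correlate effects across taxa — an explicitly unmodelled feature, and the
main reason null-calibration results here do not guarantee calibration on
real data.

The treatment acts only in manipulation-after cells: increasers (and new
colonists) are multiplied by `treatment_multiplier` (default 3, mid-range
of the large effects such supplementation experiments report), decreasers
by its reciprocal. New colonists are structural zeros everywhere except the
reference sites (their source population) until they appear at manipulation
sites after treatment; lost taxa are structural zeros at
manipulation-after. Default class fractions (30% increasers, 10% new, 5%
decreasers, 5% lost, 50% non-responders) mirror a strongly responding
assemblage in which roughly half the common taxa react, mostly positively.

Detritus standing stock is lognormal (median 100 g m⁻², log-sd 0.35) with
river effects (sd 0.25) but **no persistent site effect and no systematic
seasonal trend**: standing stocks are redistributed by spates between the
two sampling occasions, so between-period persistence at a site is weak.
Reference sites carry uplifts (detritus ×2, abundance ×1.5, retentive
coverage ×1.5) so equivalence tests have a meaningful target. Transect
surveys draw a trapping efficiency per element type (TE ~ N(0.30, 0.10)
clipped at 0, m detritus per m element), site coverages and per-transect
intercepts from gamma distributions (truncated at the transect length), and
per-element detritus lengths with mean intercept × TE — so the estimator's
target quantity is the generating parameter by construction.

None of these values is reported by the motivating study; all are declared
here once, on realism grounds, and the acceptance checks are run at these
defaults (the responder-recovery check uses its stated 10-increaser /
2-new / 3-lost scenario). Randomness flows from one root seed through named
substreams (design / abundance / transects), so identical config + seed is
byte-identical and each table can be regenerated independently.

## Retentiveness indices

LCI is the mean over a site's transects of intercepted length / transect
length, per element type (absent elements count 0); detritus LCI likewise.
TE is the ratio of summed detritus to summed intercept per site, averaged
across sites — ratio-of-sums first, because per-transect ratios are
undefined on zero-intercept transects — with sites lacking the element
excluded, and by default averaged within rivers (whether the original
values pooled across rivers is not stated; `scope='global'` is the switch).
Elements with coverage but no defined TE raise an error rather than being
dropped, since silently dropping them would bias effective retentiveness
comparisons. Standing stock divides pooled dry mass by the pooled sampled
area (1.485 m²). Detritus LCI (m/m) and mass (g m⁻²) are kept as two
separate responses throughout.

## Problem sizes and numerical choices

The default test-suite and acceptance-script problem sizes are the design's
own: 6 rivers × 7 sites × 2 periods, 80 taxa, 8 transects. Calibration
suites use 500–1000 replicates with 199 permutations per PERMANOVA (the
package default is 9999, used for single analyses); recovery suites use
100–500 replicates. Detritus-only loops simulate 5 taxa since the count
stream does not enter that response. Degenerate inputs are handled
explicitly: constant responses report missing F; zero residual MS with
non-constant data is an error; all-zero community samples are excluded with
a warning; ties in the smallest-|ES| exclusion break alphabetically.

## Known limitations

* Site effects that are shared across taxa (or persistent for detritus)
  would make the a priori contrast anticonservative; the package implements
  the published contrast faithfully rather than replacing it with the
  site-effect-free interaction contrast (x̄_AM − x̄_BM) − (x̄_AC − x̄_BC).
* The composition-equivalence bootstrap ignores dependence among
  similarities sharing a site.
* P values for the River × Treatment and three-way PERMANOVA terms rely on
  Freedman–Lane residual permutation and are approximate.
* The generator has no spatial autocorrelation between sites (the design's
  1 km spacing is taken as giving independence), no hydrological dynamics,
  and no abundance–occupancy structure beyond the lognormal baselines.
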