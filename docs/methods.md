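# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Synthetic cohorts

The simulator is the package's study system. Each deployment gets a
movement path, a depth time series, a body-composition record and a tag
fate, all from one seeded generator (`numpy.random.default_rng`); a given
seed reproduces every output byte-for-byte.

**Geography.** A colony at 37° N, 122° W; a straight 200 m shelf isobath
along the 123° W meridian (so distances to it are checkable by hand); a
flat 250 m shelf east of the isobath ramping to a 3800 m abyssal plain
over 60 km to the west; three rectangular ecoregions (California Current,
Subarctic Pacific, North Central Pacific) written as GeoJSON.

**Movement.** A two-state correlated walk in the colony-centred
azimuthal-equidistant plane: directed transit toward a sequence of patch
centres (speed ~5.5 km/h, small heading noise) and area-restricted search
(ARS) on the patch (speed ~0.8 km/h, large turning angles). The ARS hours
are the ground-truth foraging periods, which is what makes the 2 km/h
foraging-speed rule downstream meaningful. Males' patches sit just
inshore of the shelf edge; female patches lie offshore at
strategy-specific ranges. ARGOS fixes are sampled at ~1.5 h mean
intervals with class-dependent Gaussian error (3: 0.25 km … B: 10 km),
mirror ("alternate") solutions, and a 2% rate of 100–250 km outliers.

**Dives.** Four archetypes built sample-by-sample at 8 s (configurable
1–8 s): V-shaped transit dives (fixed 1.3 m/s vertical rate, ≥66 s);
pelagic foraging dives with a flat bottom phase carrying triangular
"wiggles" (amplitude 8 m) and a diel depth offset (deeper by day);
benthic foraging dives whose maximum depth tracks the local seafloor to
within ~2–4%; drift dives with a slow (0.12 m/s) monotone segment
occupying half the dive. Individuals differ: per-animal, per-archetype
multipliers on depth and duration (s.d. 5%), bottom-fraction and
wiggle-count offsets, and a personal benthic depth fraction. Guard rails
keep archetypes mutually distinguishable — non-benthic dives stay above
half the local seafloor depth, benthic foraging only happens on the flat
shelf (not the slope, where the seafloor under a moving animal changes
too fast to define a stable target depth), and wiggle counts are capped
so each wiggle spans at least six samples (faster wiggles alias into an
apparently flat bottom at the TDR sampling rate). Depth noise is
additive Gaussian (default 1 m), with an optional slow surface-offset
drift to exercise the zero-offset correction.

**Body composition.** Departure mass and trip mass gain are drawn from
per-strategy normal distributions whose defaults are the field-scale
means and s.d.s for adult males (1074 ± 194 kg departure, 458 ± 218 kg
gain), post-breeding females (335 ± 49, 76 ± 31) and post-moult females
(281 ± 36, 233 ± 53). The measured arrival mass is produced by solving
the onshore-loss model backwards (census mass such that the correction
recovers the true arrival mass exactly), so the bioenergetics round trip
is an identity check of the correction code, not of the generator.

**Tag fates.** Per-sex death (0.44/0.12) and tag-failure (0.21/0.13)
probabilities; failures are either resighted in a later season or show a
monotone location-class decline over their final 30 days; deaths stop at
sea with trend-free quality. The packaged 217-deployment fixture is a
deterministic version of the same construction with exact counts
(males 39/25/8/17, females 178/46/24/22 for
deployed/stopped/failed/died); death records use palindromic daily class
sequences, whose Mann-Kendall S statistic is identically zero, so the
degradation test can never fire on them by chance.

**What the generator does not emulate:** ocean currents and prey fields,
ARGOS error heavy tails (errors are Gaussian per class), haul-out
behaviour, emigration, or any correlation between body condition and
fate. Passing tests therefore demonstrate that the estimators recover
what the stated models put in — not that those models exhaust real
biologging data.

## Track processing

The speed/distance/angle filter removes fixes implying great-circle
speeds over 12 km/h or spike geometry (inner turning angle < 160° with
both adjacent displacements longer than an hour's travel at the maximum
speed — the conjunction reads the angle criterion conservatively, since
applying it to a single segment is ambiguous). When a flagged fix has an
alternate ARGOS solution that passes both criteria, the alternate
replaces it. Removal is iterative, worst-offender-first; the filter is
idempotent and guarantees no post-filter segment exceeds the speed cap.

Smoothing uses the integrated Ornstein–Uhlenbeck ("continuous-time
correlated random walk") state-space model per axis in the
colony-centred planar projection: velocity autocorrelation β, process
variance σ², and a global scale on the class-specific measurement s.d.s
are fitted by maximum likelihood through the Kalman filter (Nelder–Mead
on log-parameters, two starts, observations thinned to ≤600 for the
fit), then an RTS smoother is run over the union of fix times and
on-the-hour output times. The fitted error scale lets clean tracks
collapse to near-exact interpolation (< 1 m on noise-free hourly input).
If the likelihood is non-finite the stage falls back to piecewise-linear
interpolation with a warning. Repeat deployments of one animal keep the
first trip (deterministic; a seeded random mode is available).

## Dive processing

Depth series are subsampled to 8 s, zero-offset corrected by subtracting
a rolling 2 h surface minimum, and segmented at a 2 m surface threshold;
dives are retained when they exceed 32 s and 15 m. The bottom phase is
the longest contiguous run deeper than 80% of maximum depth (a common
biologging convention; configurable). Vertical excursions count
shallow-ward monotone runs within the bottom phase with amplitude ≥ 5 m
that reverse back toward depth — a proxy for prey-capture attempts; the
terminal ascent is not a reversal. Classification is hierarchical:
drift (a smoothed, 24 s-lagged vertical rate stays within ±0.4 m/s with
one sign and a real net drift ≥ 0.02 m/s over ≥ 40% of the dive), then
benthic (maximum depth within 10% of the georeferenced seafloor depth
and bottom fraction ≥ 0.15), then pelagic foraging (≥ 1 excursion and
bottom fraction ≥ 0.15), else transit. Day/night comes from the NOAA
solar-position approximation at the dive's midpoint (zenith ≤ 90° = day;
a civil-twilight 96° option exists). Dives are georeferenced by linear
interpolation of the hourly track at the midpoint time, clamped up to
2 h past the track ends.

## Foraging variables

A position is a foraging location iff its transit speed is below 2 km/h
and at least one pelagic- or benthic-foraging dive falls in its hour.
Trip-level variables: proportion of time feeding (foraging hours over
at-sea hours); mean great-circle distance of foraging locations to the
200 m isobath (foraging locations only — the alternative, all locations,
is a config away); the 95% UD foraging area from a Gaussian KDE on a
2 km grid with Silverman bandwidths in a local projection; trip typology
("focused" when fewer than five foraging locations fall outside the
farthest-point plateau, defined as hours at ≥ 90% of the trip's maximum
colony distance); majority (≥ 50%) ecoregion; and habitat class with
on/near-shelf meaning ≤ 30 km and coastal/open-ocean cutoffs at 90%/10%
of foraging locations. The 31-variable profile adds the four dive-type
proportions and the six dive metrics for both foraging dive types split
by day/night; empty cells are explicit NaN.

## Bioenergetics

Females lose 0.51 + 0.0076 × mass kg per fasting day ashore, males
multiplier × 293.1 × mass^0.75 kJ/day (2× Kleiber basal while moulting,
3.1× while breeding; the Kleiber coefficient is not printed in the field
literature we follow and is config-exposed), converted to tissue via a
93%/7% lipid/protein fuel mix (config-exposed). Corrections iterate
day-by-day on the declining mass; post-moult females get their pup's
mass added back before correction. Energy gain assumes adipose tissue is
90% lipid (37.3 kJ/g) and lean tissue 27% protein (23.5 kJ/g). The eight
foraging-success metrics divide gains by trip days or by feeding days
(proportion feeding × trip days); zero feeding days flags the relative
rates as undefined.

## Strategy clustering

Rows missing more than half the 31 variables are dropped; remaining gaps
are imputed by regularized iterative PCA (rank from the retention rule,
singular values shrunk by the mean discarded singular value, ≤ 100
iterations, tolerance 1e-6). PCA is on the correlation matrix;
components with eigenvalue ≥ 1.0 **and** ≥ 10% of variance are retained,
with a deterministic sign convention (largest-|loading| positive).
Clustering is Ward (the D2 variance criterion — the common "Ward's
method" is ambiguous between D and D2) on Euclidean distances over the
retained scores; k maximizes average silhouette over 2–8 (ties to the
smaller k), with within-cluster sums of squares reported for elbow
reading. Per-variable discrimination uses Gaussian identity-link GLMs
(cluster as categorical predictor) with small-sample-corrected AICc,
likelihood-ratio tests against the intercept-only null, Wald ANOVA (the
F equals the one-way ANOVA F) and Tukey-HSD contrasts; singleton
clusters flag the contrasts unstable. Diel comparisons run Shapiro–Wilk
on each side, Welch's t when both pass, Mann–Whitney otherwise, with
Bonferroni correction across whatever family is run together.

## Utilization distributions and overlap

UDs are binned Gaussian-product KDEs (histogram convolved with the
kernel) on regular lattices padded three bandwidths beyond the data.
Bandwidths come from a one-stage direct plug-in selector per dimension
(normal-scale ψ₆ pilot, kernel estimate of ψ₄, then the AMISE-optimal
h), i.e. a diagonal bandwidth matrix; full-matrix plug-in selection is
out of scope, and Silverman's rule is the recorded fallback. For 3D UDs
the depth axis is converted to km first so no axis dominates the
selector, and each foraging location carries its deepest foraging dive.
Level regions are highest-density cell sets reaching the target mass;
areas/volumes are cell counts × cell measure. Percent overlap compares
the intersection of two groups' level regions with each group's region.
UDOI is (measure of cells where both densities are positive) × ∫f·g,
which is exactly 1 for identical uniform distributions, 0 for disjoint
support, and can exceed 1 for concentrated shared use. Misaligned
lattices are linearly regridded onto a common lattice at the finer cell
size.

## Mortality

Tag-fate decision order: transmitted to return → survived; stopped but
resighted later → tag failure; stopped, unresighted, with a one-sided
Mann–Kendall trend (p < 0.05) toward worse daily best location classes
over the final 30 transmitting days → tag failure; otherwise presumed
dead. The 30-day window and the 0.05 level are declared stand-ins for a
qualitative "degraded over time" judgement. Tags are "stopped at sea"
when the last transmission precedes the scheduled return by more than
1.5 days. In the mortality regression, tag-failure animals (resighted or
not) are coded survived = 0 — this reconciles the modelled probabilities
with the simple death fractions (17/39, 22/178). Candidate logistic
models are all subsets of {sex, trip, year} containing sex, with year a
factor; an "individual" effect is unidentifiable with one observation
per deployment and is excluded. Models are ranked by AIC (ΔAIC ≤ 7
shortlist); the best model gets a likelihood-ratio test against the
null, a Hosmer–Lemeshow test (10 fitted-risk groups, df = g − 2) and a
per-term Wald ANOVA. Complete separation falls back to an L2-penalized
fit kept for inspection but ranked last. Sex-specific probabilities are
estimated-marginal-means style: the linear predictor averaged over the
other factors' levels with a Wald interval on the link scale,
back-transformed. Death-location comparisons (shelf distance, transit
rate) use Mann–Whitney with Bonferroni correction.

## Problem sizes and determinism

Tests and the acceptance script run scaled-down cohorts: 2–12 day trips
with foraging ranges shrunk by a common factor (so the male <
post-breeding < post-moult range ordering survives), 5–30 animals. The
planted-recovery check uses a dedicated three-strategy configuration
with generously separated dive parameters (300/550/800 m pelagic depths,
14/22/32 min durations, distinct wiggle rates and drift depths) and six
animals per strategy; the default configuration keeps the subtler
field-scale contrasts, under which the two female strategies are not
reliably separable at desk-scale cohort sizes. All randomness flows from
a single seed per run; reruns are bit-identical.

## Limitations

Great-circle distances use a spherical Earth (mean radius 6371.0088 km;
< 0.5% from ellipsoidal geodesics). The CTCRW smoother fits a single
(β, σ²) per deployment — no behavioural-state switching inside the
smoother, and no multiple imputation of tracks. The dive classifier is a
declared four-rule hierarchy, not a reimplementation of any unpublished
toolbox; boundary cases (benthic-looking dives over unknown seafloor)
default away from benthic. UD percent overlap depends on the evaluation
lattice extent only through the level regions; UDOI's support term uses
strict positivity, so it reflects the evaluation window for long-tailed
densities. Bootstrap cluster stability and model-based clustering are
out of scope.
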