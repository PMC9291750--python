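# Methods

This note documents the models and procedures implemented in
`dispersalkit`, the assumptions behind them, the parameters that matter, and
the design choices made where the problem admitted more than one reasonable
answer. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dispersal definitions

A calf's dispersal outcome is the cross of two binary classifications.

**Social dispersal** is a permanent post-weaning switch of community
association. Each detection of a calf is assigned to the adult-female
social community holding the plurality of the adult females in its group
(ties and adult-free groups are `UNASSIGNED` and ignored downstream). The
natal community is the modal assignment among detections at or before the
maximum weaning age of 18 months, with ties broken in favour of the
earliest assignment — before weaning a calf travels with its mother, so
these assignments proxy the mother's community. Scanning the assigned
sequence:

* always natal → no social dispersal;
* non-natal spells followed by a later natal detection → exploratory
  visits, no social dispersal;
* a terminal run of non-natal assignments beginning after 18 months →
  social dispersal, aged at the first detection of that run.

A terminal run of length one is counted as social dispersal in headline
outputs but carries a `single_terminal` flag, because a single sighting
cannot distinguish permanent settlement from a late exploratory visit.
Calves with fewer than two assigned detections, or no assigned pre-weaning
detection, are `undetermined` and excluded from models by default.
An apparent switch at ≤ 18 months is not counted as dispersal: the natal
assignment itself is unreliable that early. A `unanimous` assignment rule
(assign only when all adult females agree) is available behind the
`method` switch of `assign_detection_community`; plurality is the default.

**Spatial dispersal** is sustained net displacement beyond the scale of an
adult-female home range. Net displacement is the Euclidean distance from
the calf's first detection to each later detection, in a local
transverse-Mercator projection (WGS84; forward/inverse round-trip error is
well under a metre at study scale). The threshold radius for a community is
r = sqrt(Ā/π), with Ā the mean 95% kernel home-range area of its member
adult females — the radius of the circle with the average member's range
area. Classification:

* final detection within the threshold → non-disperser; every
  beyond-threshold excursion is a sortie (dated by its first detection);
* final detection beyond the threshold → confirmation by smoothing: a
  local-linear tricube smoother (span 0.5) is fitted to distance versus
  age, and the calf is a spatial disperser only if more than half of the
  detections from the start of the smoothed line's *final*
  above-threshold spell onward are themselves beyond the threshold.
  Otherwise the exceedances are sorties. The dispersal age is the first
  observed exceedance at or after that crossing.

Two deliberate choices here: the crossing anchors on the final
above-threshold spell of the fitted line, not its first crossing, because
with a wide local-linear window a large late relocation lifts the fitted
curve above the threshold near age zero and would backdate the dispersal
age into infancy; and the span default is 0.5 because at 0.75 a sustained
excursion confined to the last quarter of a ~30-point series is smoothed
below the threshold and missed entirely. The span remains a parameter.
With fewer than 4 detections the smoother cannot be fitted and the
final-distance rule decides, flagged low-confidence. Sorties before 8
months of age are attributed to travel with the mother and excluded from
the first-sortie age by default (toggleable).

The 2×2 of flags gives the four classes none / social / spatial /
social-and-spatial; the classification is exhaustive and mutually
exclusive.

## Association network

The network uses the gambit of the group on adult females only. An adult
female is an individual whose first sighting carries the field age class
"adult" (or an estimated age ≥ 48 months); conditioning on the *first*
sighting keeps maturing calves out of the reference network. The simple
ratio index is x / (x + y_ab + y_a + y_b): x counts groups containing both
individuals, y_a and y_b occasions where only one was seen, and y_ab
occasions where both were seen in different groups — so the denominator is
the number of sampling occasions in which either was seen, and 0/0 is 0.
y_ab is included in the denominator deliberately (the survey design detects
most individuals per occasion, so being seen apart is informative).
A minimum-sightings filter before networking is exposed (`min_sightings`,
default 0).

Communities are found by maximising weighted Newman modularity with the
Leiden algorithm (iterated greedy local moving with refinement and
aggregation, run to convergence, fixed seed). Plain agglomerative merging
was tried first and hit its known resolution limit — with twelve
similar-sized communities it merges adjacent pairs; Leiden recovers planted
partitions exactly in the same networks, at higher modularity. The
partition's stability is assessed by re-deriving it in contiguous temporal
blocks and reporting pairwise adjusted Rand indices plus the weighted
assortativity of the full-data labels on each block's network.

## Kernel home ranges

The 95% home range of an adult female is estimated with a Gaussian product
kernel using the bivariate-normal reference bandwidth h_j = σ_j·n^(−1/6),
evaluated on a 200×200 grid padded by three bandwidths; the area is that of
the smallest set of grid cells holding 95% of the (grid-normalised) mass.
Because the kernel inflates each axis variance by h_j² (a relative bias of
n^(−1/3), ≈ 8% at n = 2000), the locations are shrunk about their centroid
by sqrt(1 − n^(−1/3)) before smoothing, which makes the smoothed density's
dispersion match the sample's. On bivariate-normal truth the resulting
area is within a few percent of the closed form 5.991·π·σ² (the χ²₂
0.95-quantile); at survey-realistic sample sizes (n ≈ 40 locations) a
residual downward bias of order 5% in the radius remains. Individuals
with fewer than `min_locations` (default 10) sightings, or a degenerate
point cloud, are excluded from the community mean; a community with no
usable member estimate receives the global mean radius with a warning.
Per-member-then-mean is the default aggregation; pooling locations across
members before the kernel is deliberately not done, since it conflates
range size with community spread.

## Photogrammetric ageing

Height follows a sex-specific von Bertalanffy curve
h(a) = H∞ − (H∞ − h0)·e^(−k·a) with defaults h0 = 180 cm,
H∞ = 430 cm (F) / 500 cm (M), k = 0.045 month⁻¹, all overridable; the
simulator shares the same curve so the inversion is self-consistent end to
end. These defaults are plausible placeholders for giraffe growth, not
literature estimates — analyses of real data should substitute calibrated
parameters. Single heights are inverted exactly; heights at or above the
curve's value at 48 months are censored at 48 months (the curve carries no
information there), implausible measurements (≤ h0/2 or non-finite) are
rejected, and sub-birth-height noise clips to age 0. Because the curve
flattens (≈ 1.4 cm/month at 46 months), single-height inversion is noisy
exactly where dispersal happens; the pipeline therefore fits each young
individual's *birth date* by least squares across all its height
measurements (the steep early curve dominates the fit) and derives ages
from the survey calendar, which recovers birth dates to well under a month
at survey-realistic noise (10 cm SD).

## Statistical stage

The inclusion filter keeps calves first sighted as calves within the
birth-year window and detected at least once in every rolling 3-year
interval spanning the study — enough follow-up to observe natal dispersal.

*Sex differences* use logistic regression with a Gaussian random intercept
per natal community, fitted by maximising the exact marginal likelihood
with adaptive Gauss–Hermite quadrature (15 nodes recentred at each
community's posterior mode and rescaled by its curvature; β and log σ
optimised jointly by L-BFGS-B; standard errors from the numerical Hessian).
Complete separation triggers a ridge-penalised refit, flagged. At σ → 0
the fit coincides with plain logistic regression.

*Dispersal type* uses a multinomial logit with "none" as the reference
level; exponentiated coefficients are relative risk ratios. Continuous
design columns are z-scaled internally for optimisation stability and the
coefficients (and their covariance) mapped back to the raw scale exactly,
so reported effects are per original unit (e.g. per km of distance to
town). Predicted probability curves use observed-value averaging: the
focal covariate is set to each grid value for every observed record and
the class probabilities averaged within sex; they sum to one by
construction and are flat at the category frequencies for the null model.

*Distance and age* are ordinary Gaussian linear models.

Model sets are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike
weights. k counts every estimated parameter: all outcome-specific
coefficients for the multinomial, the residual variance for linear models,
the random-intercept variance for the mixed logistic. The 20-model a
priori set is a reconstruction — null; each of sex, forage, dist_town,
dist_boma, density alone; sex plus each covariate; sex×dist_town and
sex×density; all six covariate pairs; and two three-term models — and any
candidate containing a covariate pair correlated |r| > 0.5 in the data at
hand is dropped at fit time with a warning. p values are two-sided throughout
and uncorrected for multiplicity. Welch's t (Satterthwaite df) and the
tie-corrected, continuity-corrected normal-approximation Wilcoxon rank-sum
test are provided as the two-sample utilities.

## The synthetic society

The generator (`simulate_society`) reproduces the statistical structure the
analysis assumes, with every draw a deterministic function of the config
seed.

* **Space and movement.** Communities sit on a grid with 6 km spacing;
  each adult female has a fixed home-range centre (community centre + 1 km
  scatter) and per-occasion location N(centre, σ²I) with σ = 2.5 km, so
  the true 95% range is analytically known (area 5.991πσ² ≈ 118 km²,
  radius ≈ 6.1 km — matching field-scale giraffe ranges of ~115 km²) and
  the generating threshold radius is sqrt(5.991)·σ. Calves use a smaller
  scatter (1.5 km), and before weaning they stay in the core of the
  mother's range (crèche behaviour) while sharing her group; young range
  less widely than foraging adults, and this keeps a non-disperser's
  displacement series from being dominated by the mother's day-to-day
  travel.
* **Calendar and detection.** 7 years × 3 survey seasons × 2 consecutive
  secondary samples = 42 occasions (a robust design); detection is
  Bernoulli(0.9) per occasion.
* **Groups.** Community members are partitioned each occasion by a
  Chinese-restaurant process (concentration 8, giving realistic
  fission–fusion group-size variation with mean size ≈ 4); each group
  merges with a random group of the nearest neighbouring community with
  probability 0.02 per occasion. The mixing rate is an assumption, not an
  estimate: overlapping communities are described in this study system as
  rarely or never seen together.
* **Calves and fates.** 200 calves are born uniformly over the first two
  study years with 1:1 sex ratio; fates are drawn per sex from the
  published class frequencies (males 0.31/0.18/0.12/0.39,
  females 0.74/0.06/0.13/0.07 for none/social/spatial/both), optionally
  tilted by community covariates through a multinomial-logit link.
  Dispersal ages are N(46, 13) months truncated below at 20 and above so
  the switch falls at least ~10 months before the study ends — the
  simulator plants only dispersal the survey could in principle observe,
  mirroring a field study's inability to classify what happens after its
  last season. At the planted age the fate executes instantaneously:
  social dispersers switch group sampling to the nearest neighbouring
  community and shift their centre 0.4 threshold radii toward it; spatial
  dispersers relocate 2.0 threshold radii in a random direction while
  keeping natal group sampling; social-and-spatial dispersers relocate 2.5
  radii and switch. These displacement factors reproduce the observed
  ordering of class-conditional final distances (none < social < spatial <
  both, roughly 3 / 4 / 12 / 15 km against a ~6 km threshold).
* **Sorties** occur with probability 0.02 per pre-dispersal occasion (from
  age 2 months): a single-occasion excursion to 1.5 threshold radii with
  return. Heights are curve values plus N(0, 10 cm) noise; field age
  classes are derived from true age.

What the generator does **not** emulate: temporally autocorrelated
movement (locations are independent draws, so home ranges are sampled
faster than in real telemetry), community turnover or range drift, adult
males and hence bachelor herds (the bachelor-herd utility is tested on
constructed fixtures), mother–calf separation before weaning, uneven
survey effort, and misidentification. Passing recovery tests therefore
shows the pipeline is correct under its own assumptions — stable
communities, detection missing completely at random, instantaneous
dispersal — not that those assumptions hold in any particular field
system.

## Numerical and degenerate-input conventions

Ties in the plurality vote and in natal-mode selection resolve as
described above; the Leiden seed defaults to 0 and community labels are
canonicalised by size then smallest member ID; SRI 0/0 is 0 and the matrix
is symmetrised exactly; lowess runs with zero robustness iterations so the
fit is deterministic; quadrature uses 15 nodes (results are insensitive to
more for community counts this small); the multinomial optimiser is BFGS
on z-scaled columns; AICc is +∞ when n ≤ k + 1, which pushes
over-parameterised models to the bottom of a small-sample ranking rather
than crashing it. Empty networks, all-identical point clouds, constant
responses, single-detection calves and empty outcome categories raise or
warn explicitly rather than propagating NaNs.

## Known limitations

* Threshold radii inherit the small-n kernel bias noted above; with ~40
  locations per adult the estimated radius runs ~5% low. The
  classification margin in the simulator is wide enough that this does not
  move classes, but real analyses near the threshold should treat radii as
  having that uncertainty.
* The single-terminal-sighting convention (count as social disperser,
  flagged) biases social-dispersal counts upward in sparse data; the flag
  exists so users can do the sensitivity analysis.
* The candidate model set is a reconstruction; users with a registered a
  priori set should pass their own specs to `fit_model_set`.
* Growth-curve defaults are placeholders shared with the simulator, not
  calibrated estimates.
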