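# Methods

This note documents the models, calibration and numerical choices behind
`langlat`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Measures

**Network task asymmetry.** For a task contrast (sentence minus word-list
production, listening or reading), per-hROI left and right BOLD values are
differenced pairwise and combined as a volume-weighted mean over a region
set: `asym = Σ wᵢ (Lᵢ − Rᵢ) / Σ wᵢ`. The pair weight is the *sum* of the
pair's two hemispheric volumes — symmetric under hemisphere exchange, so
swapping all left/right values exactly negates every asymmetry. The
asymmetry is a raw difference, not a normalized laterality quotient: the
0.05 dissociation band and the calibration tables live on this scale.
Region sets: SENT_CORE (all 18 pairs) and SENT_HUBS (F3t, STS3, STS4).
The bundled atlas carries synthetic but plausible volumes (uniform
1000–9000 mm³, fixed once); real volumes can be supplied as a TSV and all
operations take volumes from the atlas, never from constants.

**Resting-state metrics.** Series are cleaned by OLS confound regression
(intercept and linear trend always included; optional user confounds;
rank-deficient designs drop redundant columns with a warning), then
filtered with a least-squares linear-phase FIR bandpass (default
0.01–0.1 Hz) applied forward–backward (zero phase; the effective amplitude
response is the squared design magnitude). The filter order is about four
cycles of the low cutoff (`numtaps ≈ 4/(low·TR)`, rounded odd, 201 taps at
the defaults). Transition bands are specified as explicit least-squares
ramps: left as "don't-care" regions, the LS design grows ~10× gain spikes
inside them, which would let a narrow band dominate the filtered variance
and visibly bias sample correlations. With the ramp design the maximal
gain is ≈1.01 and the empirical correlation bias at n = 240 is below
0.005.

Degree centrality of an hROI is the sum of its *positive* correlations
with the other 17 ipsilateral network hROIs (negative correlations
contribute zero), averaged over a hemisphere's 18 hROIs; the left/right
mean, sum and difference (asymmetry) are derived from the two hemisphere
values. A `dc_partners="all"` flag preserves the alternative reading in
which contralateral hROIs also count. The homotopic correlation Rs_mIHHC
is averaged on the Fisher-z scale and back-transformed for reporting;
after per-column standardization the r/z choice is immaterial for
clustering.

**Classification.** The nine clustering variables are the six signed task
asymmetries, the Rs_DC sum, the Rs_DC asymmetry and Rs_mIHHC, each
z-scored (sample sd). Ward minimum-variance agglomeration on Euclidean
distances (the ward.D2 criterion) builds the tree; twelve internal
validity indices (Calinski–Harabasz, silhouette, Davies–Bouldin, Dunn,
C-index, McClain–Rao, point-biserial, PBM, gap statistic with a uniform
box reference and the Tibshirani one-standard-error rule, Xie–Beni,
Ratkowsky–Lance, Ball–Hall difference) each vote for their optimal k over
cuts at k = 2…8; the modal k wins, ties to the smallest k. For k = 3 the
cluster with the lowest mean task asymmetry is labelled ATYP (with an
`_unverified` suffix and a warning if that mean is not negative); the
higher-PROD remainder is TYP_STRONG and the other TYP_MILD. The pipeline
reports the voted k but labels groups at a configurable `label_k`
(default 3), since the downstream analyses are defined on the three
canonical phenotypes.

**Dissociations.** Each task × region-set asymmetry gets a direction label
(L if ≥ +0.05, R if ≤ −0.05, else N). A participant is CROSSED when at
least one region set carries both an L and a R; neutral-band tasks never
trigger a dissociation on their own (`dissociation_rule="one_pole"`
preserves the stricter alternative in which any opposite-signed task
opposes a supra-threshold one).

**Group statistics.** Repeated-measures MANOVA uses the multivariate
approach: between effects are tested on subject means, within effects on
orthonormal difference contrasts of the repeated measures, through a
sum-coded linear model so each term's test is Type III (the groups are
unbalanced). Pillai's trace is reported with the standard F
approximation; its type-I error is verified by simulation (1000 null
replicates, rejection rate within [0.03, 0.07] at α = 0.05), and the
between-subject tests agree with statsmodels' MANOVA to 1e-8. Post hocs
use Tukey's HSD; proportions use Pearson's chi-square without continuity
correction. PCA of the cognitive residuals eigendecomposes the
correlation matrix; the scree criterion is operationalized as the
acceleration elbow (largest drop of successive eigenvalue differences),
accepted only when unique and consistent with the Kaiser line — a steep
first eigenvalue otherwise yields a spurious one-component elbow — with
the Kaiser count as fallback; retained components are promax-rotated
(varimax with Kaiser row normalization, then the standard promax
transform with power 4). Variance explained is reported pre-rotation.

## The synthetic cohort

The generator emulates the study conditions: 287 participants
(150 left-handers, 140 women), latent groups TYP_STRONG/TYP_MILD/ATYP of
125/132/30 with left-hander quotas 58/67/25, female quotas 48/77/15, and
planted CROSSED members 2/9/12 (17 left-handed, with the ATYP crossed
split 10 left- / 2 right-handed). All quotas are exact counts, not
Bernoulli draws, so the printed proportions are reproduced
deterministically. Demographics: age 25.8 (6.5) years, education 15.6
(2.3) years, Edinburgh score N(−63.2, 39.9) for left-handers and
N(90, 12) for right-handers (the right-hander parameters are not printed
anywhere; these are realistic for a self-declared right-handed sample),
all clipped to [−100, 100].

**Task contrasts.** Per participant and task, target SENT_CORE and
SENT_HUBS asymmetries are drawn from the group's published (mean, sd);
per-hROI left/right values then solve the volume-weighted-mean constraint
in closed form (hub pairs carry the hub target; non-hub pairs the
compensating constant), and per-hROI noise with zero volume-weighted sum
within each subset is added, so the recomputed network asymmetries equal
the drawn targets to machine precision. CROSSED members receive
truncated-normal targets planted beyond the band in the documented
patterns (ATYP majority: PROD leftward, LISN/READ rightward; 3 of 12
reversed; TYP_MILD: READ flipped, TYP_STRONG: LISN weakly flipped — for
TYP members the flip is planted in SENT_HUBS with SENT_CORE in the
neutral band, matching the greater sensitivity of the hub measure).
CONGRUENT members are drawn with rejection against the dissociation rule,
and their cell means are analytically re-centred (truncated-normal
expectations) so that every group × variable mixture mean still equals
the published cell. Within-cluster residuals of the six targets are
independent by default (`task_corr`/`roi_set_corr` re-introduce a common
residual trait if desired): the shared lateralization trait is absorbed
by the cluster means, and independence is the structure under which the
planted partition is recoverable at the published effect sizes.

**Resting series.** Each group has a block correlation template: uniform
within-hemisphere correlation r = targetDC/17 per hemisphere (the closed
form of the degree-centrality definition under uniform positive r),
homotopic diagonal equal to the target Rs_mIHHC, heterotopic entries 0.8×
homotopic (they enter no metric; the ratio only affects positive
semi-definiteness). Participant-level jitter perturbs the template
through a common within-hemisphere shift, a left/right differential shift
and a homotopic shift, with sds derived from the published
between-participant spreads minus a fixed sampling allowance — a single
scalar jitter cannot match the published sds of the Rs_DC mean (~1.4) and
asymmetry (~0.77) simultaneously. A jittered matrix that loses positive
semi-definiteness has its *jitter* shrunk (×0.7 until PSD): repairing the
matrix by eigenvalue clipping instead would bias the group means (≈−0.6
on mean Rs_DC in early experiments). The PSD feasibility region is
one-sided, which leaves a small upward truncation bias (~+0.2) on the
ATYP mean Rs_DC — within the two-standard-error calibration tolerance.
Series are zero-mean Gaussian with stationary covariance (no
autocorrelation or artifacts: the metrics are Pearson correlations, which
are invariant to this simplification, while the bandpass is still
exercised on every series).

**Cognition.** Eleven battery scores follow a 4-factor model
(spatial, phonological, memory, verbal) with the published loading
pattern, group-level factor mean shifts from the published component
means (SPA: 0.29/−0.19/−0.41; MEM: 0.05/0.19/−0.57), small covariate
effects (age, education, sex), and uniqueness sd = 0.9 × √(1 −
communality). The canonical unit-variance split puts the weakest printed
component at the detection edge of an 11-variable PCA at n = 287
(its eigenvalue fluctuates around 1); the slightly tighter uniqueness
keeps the planted 4-component structure recoverable, which the
calibration requires, and the final scores are rescaled to the published
pooled means/sds regardless. The phonological factor (one loading above
0.5, two cross-loaded variables) is still not recoverable at 0.9
congruence by PCA at this sample size; the recovery test asserts
congruence > 0.9 for the three well-identified factors only.

**Anatomy.** GM/WM hemispheric volumes and corpus-callosum volume are
drawn per organization × dissociation cell at the published means/sds,
with left = base + asym/2 and right = base − asym/2 so the left-minus-
right difference equals the drawn asymmetry exactly. Synthetic external
labels (GMM categories with matching HFLI ranges; per-hemisphere SVM
dominance) emulate the published cross-classification counts for the
concordance examples; the external classifiers themselves are not
reimplemented.

## What the synthetic validation shows — and does not

Passing tests establish that the measures, the clustering, the
dissociation rule and the statistics do what they claim on data with the
published group-level structure, exact quotas and Gaussian within-group
variation. They do not establish behavior on real BOLD data:
no motion or physiological artifacts, no autocorrelation, no non-Gaussian
tails, and a latent three-group mixture where reality is closer to a
continuum.

One structural consequence is worth stating plainly: at the published
group means and sds, the standardized 9-variable geometry places the
ATYP centroid 4.6–6.2 sd units away from the typical groups while
TYP_STRONG and TYP_MILD are only ≈2.2 apart. Internal validity indices of
the global-optimum family therefore prefer the two-cluster cut
(ATYP vs the rest) on this synthetic geometry — the majority vote returns
k = 2, not the k = 3 of the original empirical data — even though the
three-group structure is real (a supervised oracle classifier recovers
the planted groups with ARI ≈ 0.9, and Ward's three-cluster cut reaches a
median ARI ≈ 0.7). Difference/sequential-type indices (Hartigan, Marriot,
Friedman, Duda–Hart and relatives) vote 3 more often, but not enough to
carry a mixed panel. A summary-statistics-calibrated Gaussian mixture
evidently does not preserve whichever feature of the empirical geometry
made three clusters internally optimal there; the package reports the
vote it actually measures.

## Problem sizes and determinism

Default analyses run the full 287-participant cohort with 240-timepoint
resting runs; the acceptance script uses 10 replicate cohorts for the
cluster-number vote and 5 for the calibration-recovery means, and the
test suite verifies the statistical calibration with 1000-replicate null
simulations at n = 48. All randomness flows from a single master seed
through named, independent child streams (one per generator), so every
table is byte-identical under a repeated seed.
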