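# Methods

## The problem

Focal brain damage occasionally causes remission of nicotine addiction.
Individual lesion locations are heterogeneous, so locating the responsible
substrate voxel-by-voxel (lesion-symptom mapping) fails; the working
hypothesis is that the effective lesions share a *network*: a common
profile of functional connectivity to the rest of the brain. Lesion network
mapping (LNM) tests this by using each patient's lesion mask as a seed in a
normative resting-state connectome and comparing the resulting per-lesion
connectivity maps between outcome groups. This package implements that
pipeline end-to-end — seed maps, group inference, reproducibility and
specificity tests, structural disconnection, and hub (therapeutic-target)
maps — together with a synthetic-data module that plants known effects so
every stage can be validated against ground truth.

## Lesion network maps

For lesion mask $M$ and connectome subject $s$ with time series $y_s(t,v)$
over brain voxels $v$:

1. seed series: unweighted mean of $y_s$ over in-brain lesion voxels;
2. seed map: Pearson $r_s(v)$ between the seed series and every voxel's
   series (series demeaned per voxel; zero-variance voxels get $r=0$ so
   group models keep full coverage; a constant seed series is an error);
3. Fisher transform $z_s(v) = \operatorname{atanh} r_s(v)$, with $|r|$
   clipped at $1-10^{-7}$;
4. combination across subjects: the mean of the $z_s$ maps (default), or
   optionally the per-voxel one-sample $t$ of the $z_s$ (the two are
   monotonically related under similar per-voxel subject variances). Lesion
   voxels are retained in the output; downstream masks can exclude them.

## Group inference

At each voxel an OLS GLM relates the Fisher-z value to the clinical
outcome. Outcome coding: remission = 1, quit-without-remission = 0.5,
non-quitter = 0 on one axis (a separate-dummy coding is available); study
site enters as treatment dummies, optional covariates (lesion size, age,
gray-matter proportion, insula damage) as extra columns. The tested
contrast selects the outcome axis, i.e. remission versus not quitting with
the intermediate group contributing coverage and power.

Two maps are produced:

* the **contrast effect map** $c^\top\hat\beta$ — the covariate-adjusted
  group difference in z units; this is the amplitude estimate of the
  remission network, used to compare against a planted or reference
  amplitude map (recovery, specificity reference). The $t$ map renormalises
  by per-voxel residual variance, which distorts amplitude relative to a
  loading map but *standardises* the structured between-lesion noise — so
  the cross-cohort reproducibility comparison correlates t maps, whose
  label-permutation null is far narrower than raw effect maps';
* the **t map**, enhanced with threshold-free cluster enhancement (TFCE,
  $E=0.5$, $H=2$, $dh=\max/100$, 26-connectivity — the conventional
  defaults) and thresholded by the permutation distribution of the maximum
  TFCE statistic: Freedman–Lane residual permutation under the
  nuisance-only model, identity permutation included, so
  $p_{FWE} \ge 1/(n_{perm}+1)$ everywhere. Both tails are enhanced
  separately (negate, enhance, negate back). Voxel-wise uncorrected p comes
  from each voxel's own permutation distribution of $t$.

TFCE is computed either by the definitional per-threshold
connected-component sweep or by an exactly equivalent sorted union-find
pass (numba); the two paths agree to rounding error and are cross-checked
in the tests against an independent per-voxel flood-fill oracle and against
closed-form integrals for single- and two-voxel configurations.

VLSM (the negative-control analysis) reuses the same permutation engine
with the voxel-wise regressor being lesion presence/absence; voxels
lesioned in fewer than 4 patients (or spared in fewer than 4) are excluded.

The striatal dissociation test is the 2×2 mixed-design ROI × group
interaction on mean ROI connectivity, computed as the squared pooled
two-sample $t$ on the within-lesion ROI difference — algebraically the
mixed-ANOVA interaction $F$ with df $(1, n-2)$; it is cross-checked against
`pingouin.mixed_anova`.

## Similarity, reproducibility, specificity

All spatial comparisons are Pearson correlations over unthresholded maps
within the analysis brain mask. Cross-cohort reproducibility: observed $r$
between two cohorts' contrast maps versus a null built by permuting outcome
labels *within site strata* and recomputing both maps — label permutation
(not voxel shuffling) preserves spatial autocorrelation under the null.
Specificity: each behavioral variable's voxel-wise correlation map
(per-voxel Pearson between connectivity and score across lesions) is
correlated with the reference network; only the designated target variable
receives a permutation p (score shuffling), other rows report r and rank.
The within-group pairwise-similarity comparison uses Mann–Whitney U on the
two sets of pairwise map correlations; those pairs are not independent
observations, which is a documented caveat of the statistic, replicated as
conventionally reported.

## Structural analyses

Tract damage per lesion and tract: the maximum tract probability under the
lesion (headline statistic) and the damaged fraction of the suprathreshold
(≥ 0.5) tract volume. Per-tract permutation GLMs (site and lesion size
adjusted, one-tailed: remission > not quitting) are corrected across the
tract family by the max-statistic permutation distribution. The
disconnectome score sums a lesion's disconnection-map values over the
positive, FWE-significant voxels of the functional remission network (raw
values, unthresholded — an unthresholded positive-weighted variant of the
network mask is available); the group test is the same one-tailed scalar
permutation GLM.

## Hub / target maps

Every in-mask voxel is treated as a single-voxel seed through the same
map machinery (mean Fisher-z combination), and its whole-brain profile is
correlated with the reference network. The seed's own voxel is excluded
from the correlation support via closed-form leave-one-out moment
corrections — otherwise the trivially perfect self-correlation inflates the
match. The map is thresholded at $r > 0.75$ and $r < -0.75$; peaks are
greedy local maxima of $|r|$ separated by ≥ 3 voxels, reported in world mm.
A `stride` option subsamples seeds (pure subsampling, no interpolation).

## Synthetic data: what it emulates and what it does not

The connectome generator draws, per subject, $y(t,v) = \sum_k L_k(v)\,
\xi_k(t) + \varepsilon$, with $K$ shared unit-norm spatial loading maps
$L_k$ (sums of signed Gaussian bumps, truncated at 5% of peak so the
planted support is a well-defined set of nonzero voxels; pairwise
$|r|<0.95$), i.i.d. standard-normal latent series $\xi_k$, and voxel noise
$\varepsilon \sim N(0, \sigma^2)$. Defaults: 24³ grid of 2 mm voxels with
an inscribed-ellipsoid brain mask (~6,300 voxels), $K=3$, 20 subjects ×
100 timepoints, $\sigma = 0.02$ — placing within-network voxel-pair
correlations around 0.3–0.7, the resting-state range, while keeping
seed-map estimates in the informative regime.

Lesion cohorts: spherical lesions of 30–150 voxels at uniform in-brain
centers; each lesion's network map is computed against the connectome and
its spatial correlation $s$ with the planted map sets
$P(\text{remission}) = \operatorname{logistic}(\operatorname{logit}(0.3)
+ 2.0\,(s - \bar s))$ — a base remission rate near the clinical one and a
log-odds slope of 2 per unit similarity. Centering on the cohort mean
anchors the base rate: the raw $s$ distribution inherits an arbitrary
offset from the balance of the planted map's positive and negative
regions, and without centering the realized remission rate would drift far
from the intended ~30% from world to world. A random, outcome-independent 20% of the
cohort is relabeled quit-without-remission; sites alternate round-robin.
Tracts are brain-confined persistent-random-walk tubes, Gaussian-smoothed
(σ = 1.5 voxels), max-normalised and pruned below 0.05 so support is
compact; a lesion's disconnection map is the elementwise max over tracts it
touches. Behavioral scores: one variable linear in $s$ plus noise, the
rest pure noise.

Not emulated: hemodynamics, head motion, scanner artifacts, realistic
lesion geometry, distance-dependent connectivity, and — importantly — the
high dimensionality of real cortical connectivity. With only $K$ planted
networks, label-permutation null maps are random combinations of the same
$K$ patterns, so chance spatial correlations are far larger than in real
data (the null 95th percentile sits near 0.55 at $K=3$ rather than near
0.2). Detection margins in the validation studies should therefore be read
as conservative relative to a high-rank connectome, and passing tests
demonstrate correctness of the machinery, not clinical effect sizes.

## Validation studies and problem sizes

`lesionnet.experiments` fixes the study conditions used by the test suite
and `scripts/acceptance.py`:

* **Recovery** — 120-lesion cohort, 20-subject connectome, β = 2: the
  contrast effect map correlates with the planted map (r ≥ 0.7 across
  seeds, typically 0.75–0.94) and FWE-significant voxels overlap the
  planted support (Dice > 0.3).
* **Null calibration** — 100 independent β = 0 cohorts of 60 lesions,
  200 permutations each, on a 16³ grid (the compact grid keeps 100 full
  permutation analyses to a few minutes): the family-wise false-positive
  rate stays in the binomial band around 0.05.
* **Cross-cohort reproducibility** — 20 repeats of two independent
  200-lesion cohorts from one planted effect; detection = observed r above
  the 95th percentile of the within-site label-permutation null. The
  cohort size comes from a power analysis at β = 2: the low-rank world's
  permutation null is wide (95th percentile near 0.6), so per-repeat
  detection reaches ~1 only around n = 200.
* **Specificity** — 1 linked + 37 unlinked behavioral variables; the
  linked variable should rank first against the cohort's own contrast map.
* **Disconnectome direction** — 60 lesions, half on network-feeding tract
  cores, half off them; one-tailed permutation p < 0.05.
* **Hub self-consistency** — a reference equal to one voxel's profile
  peaks at that voxel with r ≈ 1.

## Numerical choices and degenerate inputs

* Affine agreement tolerance for shared grids: 1e-4 mm; grid mismatch is a
  hard error (no resampling is ever performed).
* NaN marks out-of-analysis voxels in statistic maps; masks may not
  contain NaN. Masks are strictly {0,1}.
* Zero-variance time series → r = 0; numerically zero residual variance →
  t = 0; |r| clipped at 1−1e-7 before atanh.
* TFCE thresholds are k·dh with an epsilon (1e-9·dh) tolerance so voxels
  lying exactly on a threshold are treated identically across
  implementations.
* Permutation p-values always include the identity permutation:
  p = (1 + #{null ≥ observed}) / (n_perm + 1).
* Mann–Whitney U uses exact enumeration when n₁·n₂ ≤ 400 and tie-free,
  else the tie-corrected normal approximation.

## Known limitations

* No spatial normalisation/registration: all inputs must share a grid.
* The synthetic world is low-rank (see above); specificity and
  reproducibility margins are world-dependent.
* The hub map at stride 1 is O(V²) in time; use `stride` on large grids.
* The exact combination rule ("combined" maps), VLSM statistic, and
  case-permutation scheme of the original analyses are not fully
  specified upstream; the defaults here (mean-z, covariate-adjusted GLM,
  within-site label permutation) are declared, configurable choices.
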