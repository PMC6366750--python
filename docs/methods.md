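# Methods

This note documents the models, conventions and design choices behind
`oscpls`, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task design and analysis windows

The simulated experiment follows a two-group (younger / older adults),
204-trial visuospatial relational-memory task. Each trial presents three
study objects sequentially (onsets 0, 3, 6 s), a delay from 9 s, and a test
display from 11 to 15 s; the analysis epoch spans −2.5 to 15 s relative to
the first study onset. Analysis windows (closed intervals, seconds):

| window | interval | reference |
|---|---|---|
| pre_stimulus | [−0.75, 0] | first study onset |
| first_study | [0.25, 2.5] | first study onset |
| first_study_short | [0.25, 1.25] | response-locked baseline |
| delay | [9.75, 10.5] | 0.75–1.5 s after delay onset |
| test | [11.25, 13.5] | 0.25–2.5 s after test onset |
| response_locked | [−1.0, 0] | button press |

Two conventions for the delay comparison circulate (pre-stimulus
−0.75..0 s vs −0.25..0 s, delay 0.75..1.5 s vs 0.25..1.5 s); the first is
the default and the second can be configured through `TrialTimeline`.
Windows deliberately avoid the initial evoked response; no baseline
z-scoring per frequency is applied — conditions are compared by window
subtraction, and the evoked transient is excluded by window placement
rather than removed.

Bands: theta 2–7 Hz, alpha 9–14 Hz, beta 15–30 Hz, with a theta 4–7 Hz
variant selectable everywhere bands enter (activity below 4 Hz is
conventionally delta). Band and window bin inclusion uses **closed
intervals on bin centres**, which makes the shared band edges at 7/9 and
14/15 Hz reproducible across sampling rates.

## Spectral stage

`compute_tfr` tiles each trial with a fixed number of overlapping
Hann-tapered segments (default 512 points, 200 per trial). The hop is
derived, `hop = floor((n_samples − window)/(n_windows − 1))`, because the
analysis convention fixes the window count per trial, not the hop.
Per-segment one-sided power spectral densities are averaged over segments
and trials. Power enters downstream analyses as natural-log mean power by
default (flag for linear): planted effects and noise are then additive and
scale-free, matching how event-related power decreases/increases are
usually summarised.

## Mean-centered task PLS

The data matrix stacks participants within conditions within groups
(rows) against channel × band (columns). The group × condition cell-mean
matrix is centered on the unweighted grand mean of the cell means and
decomposed by SVD. This "grand" centering leaves both group and condition
effects expressible; a "condition" variant (per-condition mean across
groups removed, isolating group and interaction effects) is available, and
the variant used is recorded in the result metadata since several centering
conventions are in common use and the choice changes which contrasts an LV
can express. Brain scores project the subject rows, centered by the same
grand mean, onto the brain saliences; consequently the cell means of the
brain scores reproduce `U·S` exactly (verified numerically in the tests).

Sign indeterminacy is resolved deterministically: the largest-magnitude
brain-salience element of each LV is made positive.

### Permutation test

Rows are reassigned to cells without replacement, the decomposition is
recomputed, and `p_i = #{σ_i^perm ≥ σ_i^obs}/n_perm` with the literal
counting rule (an add-one smoothing option exists, off by default).
Two schemes are implemented because descriptions of the procedure often
say only "reassigned to conditions": `cells` (default) reassigns rows to
every group × condition cell, testing group and condition structure
jointly; `within_group` shuffles only within group, never moving group
membership. The scheme used is recorded in the result metadata. Note that
for `p = 0` to be attainable the counting rule requires that no permutation
reproduces the observed partition; at realistic sample sizes re-drawing
the identical partition has negligible probability.

### Bootstrap

Subjects are resampled with replacement within their group, all condition
rows of a subject moving together, holding condition assignment fixed. Each
bootstrap SVD is aligned to the original LVs with an orthogonal Procrustes
rotation before accumulating statistics — without alignment, sign and order
indeterminacy of the SVD makes element-wise standard errors meaningless.
The rotation is computed from the brain-salience block (high-dimensional,
hence stable) and applied to both brain and design saliences. Only the LVs
with non-zero singular values are aligned and summarised.

Percentile confidence intervals use order-statistic quantiles (`lower` for
2.5 %, `higher` for 97.5 %): with only two draws the interval is exactly
their min/max, and in general the interval is never narrower than the
interpolated percentile. An element is *reliable* when its 95 % CI
excludes zero; the bootstrap ratio (salience / bootstrap SE) is also
reported, with |BSR| ≥ 1.96 available as the alternative reliability rule
since "95 percent confidence bounds" is ambiguous between the two
conventions. A degenerate bootstrap draw (all-zero spectrum, e.g. zero
within-cell variance) is redrawn up to a retry cap; identical-subject
degenerate data yields zero SEs and a degeneracy flag rather than an error.

## Behavioural PLS

Pearson correlations between each behavioural measure (accuracy %, mean
correct RT ms, hippocampal volume mm³) and each brain column (a per-subject
window contrast) are computed **within group** and stacked group-wise into
a (groups · measures) × columns matrix, which is decomposed by SVD.
Measures are not standardised across groups, so group differences in
behavioural level do not leak into the correlations. Permutations reassign
behaviour vectors to subjects within group. The bootstrap resamples
subjects within group and produces CIs both for brain-salience elements and
for the per-group correlation between brain scores and each measure — the
quantity usually plotted with error bars in correlation profiles.

A caveat inherent to the procedure (shared with the standard toolbox
implementations): the per-group score–behaviour correlations are in-sample
quantities — the brain salience is fitted on a matrix that includes every
group's correlation rows — so for a group with no true coupling the
observed correlation is biased away from zero and its bootstrap CI excludes
zero more often than the nominal 5 %. In the study-scale recovery
simulation the empirical false-flag rate for the uncoupled group was
roughly one seed in ten. Group-level claims should therefore rest on the
permutation test plus the reliability asymmetry, not on a lone CI.

## Behavioural statistics

Group comparisons from summary statistics use the pooled-variance
two-sample t (df = n₁+n₂−2), reproducing the conventional df = 30 at
16 + 16 subjects; Welch's t is available by flag. The package reports t and
t² (t² being the equivalent one-way F). Accuracy counts non-responses as
incorrect — the design is forced-choice and every trial is a response
opportunity — and mean RT uses correct trials only. The response-locked
trial filter keeps correct trials with RT **strictly** greater than 1000 ms
so no maintenance-period activity leaks into pre-response windows. The
outlier rule flags values more than 2.5 sample SDs (ddof = 1) from their
group mean, candidate included; the tests document its known insensitivity
at tiny n (a single extreme value inflates the SD enough to shelter
itself).

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a fixture. Its
defaults emulate the study conditions: 2 groups × 16 subjects, 90 virtual
channels (AAL region labels, cerebellum excluded), 3 bands, 204 trials,
behaviour scales matching the published group summaries (accuracy ≈ 82 %,
younger RT ≈ 1.5 s vs older ≈ 2 s log-normal, volumes ≈ 7.3–7.6 · 10³ mm³).

*Power.* Cell mean + planted effects + Gaussian noise on log power
(linear-power mode by flag). Planted magnitudes are expressed in units of
the within-cell noise SD because no absolute amplitude scale exists for
source power; `noise_sd` defaults to 1.

*Brain–behaviour coupling.* One standard-normal latent `u` per subject
loads ±β/2 on the two contrasted phases in the coupled channels with
β = |r|·σ·√(2/(1−r²)), which makes the population correlation between the
observed per-channel contrast and the latent **exactly** r; the subject's
log-RT location loads on the same latent. Trial-level RT sampling
attenuates the realised power–RT correlation slightly below r.

*Behaviour.* Accuracy is Bernoulli per trial around a per-subject rate
(group mean plus between-subject spread — the binomial alone would give an
implausibly small between-subject SD at 204 trials); RTs are log-normal per
trial with a configurable fraction drawn below 1 s so the response-locked
filter is non-trivial, and an optional linear practice effect. Per-subject
summaries are computed by the behaviour module, exercising the real
summarisation path.

*Raw signals.* 1/f-amplitude background plus one unit-RMS band-limited
carrier per band, with per-window amplitude gains; band power in a window
scales as gain², the analytic target of the spectral recovery tests.

What the generator does **not** emulate: sensor physics, beamformer
leakage and spatial correlation between channels (channels are
independent), non-Gaussian power fluctuations, trial-to-trial power
variability within a window, and volume conduction. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
generative model, not robustness to every property of real MEG data.

## Verification battery and problem sizes

The acceptance battery (`oscpls.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) checks, at sizes
chosen to keep the full run in the tens of seconds on one CPU:

- behavioural t statistics recomputed from the printed group summaries;
- PLS core vs an independent eigendecomposition of `M_cᵀM_c` on random
  4-cell × 6-column designs (reconstruction ≤ 1e−10, salience agreement up
  to sign, crossblock sum = 100 ± 1e−9);
- Monte-Carlo permutation p vs exhaustive enumeration of all 720 row
  orderings of a 3-subject × 2-condition instance (binomial tolerance), and
  null calibration: LV1 p-values over 200 pure-noise replicates at 200
  permutations vs Uniform(0,1) by Kolmogorov–Smirnov;
- percentile-CI coverage over 300 Gaussian replicates (100 subjects, two
  conditions, six columns, contrast-to-noise high enough that the
  normalised salience is in its linear regime, n_boot = 300). At low
  contrast-to-noise the norm constraint shrinks the bootstrap spread of
  every element and the percentile interval genuinely under-covers
  regardless of implementation — that regime tests the estimator's
  small-sample geometry, not the resampling machinery, so the check runs
  where percentile intervals are first-order accurate;
- the behavioural-PLS closed form (one group, one measure:
  σ = ‖r‖₂, salience = r/‖r‖₂ to 1e−10);
- spectral accuracy: ≥ 90 % of a pure tone's power within ±2 Hz, and
  agreement with an independently coded Hann periodogram to 1e−6 relative;
- study-scale recovery (16/group, 90 channels, 3 bands, 1000
  permutations/bootstraps): a planted −1.5 SD broadband test-phase decrease
  in 30 channels for the older group is recovered with
  |corr(design salience, planted contrast)| ≥ 0.95, and a widespread
  broadband power↔RT coupling (r = 0.6 per channel, 40 channels, older
  group only) is detected as reliable in the planted group and not in the
  control group. The coupling is planted widespread because a spatially
  distributed RT-linked pattern is what the design emulates and what makes
  the behavioural LV signal-dominated at n = 16 per group; sparse couplings
  (a dozen columns out of 270) are genuinely undetectable at this sample
  size — the correlation-matrix noise rows swamp them.

## Known limitations

- Channel MNI coordinates shipped with the package are synthetic
  placeholder positions (deterministic spherical layout), present only so
  the metadata table has its documented shape; they are never used in
  computation.
- The permutation and bootstrap loops are plain Python over small SVDs;
  at the default 1000/1000 resamples and study scale a full pipeline run
  takes seconds, but very large designs would benefit from batching.
- Split-half and cross-validated PLS variants, non-rotated task PLS, and
  multi-block PLS are out of scope, as are MEG sensor-level formats and
  beamforming.
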