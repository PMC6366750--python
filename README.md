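# oscpls

Task and behavioural partial least squares (PLS) for source-space MEG band
power, with a synthetic two-group task simulator.

## What this is for

Studies of cognitive aging often compare oscillatory brain activity between
younger and older adults across the phases of a memory task: band-limited
power (theta 2–7 Hz, alpha 9–14 Hz, beta 15–30 Hz) is extracted from
beamformer virtual channels in defined task windows (pre-stimulus, study,
delay/maintenance, test, response-locked) and submitted to multivariate PLS
analyses, with behavioural measures (recognition accuracy, mean correct
response time, hippocampal volume) tied back to the brain patterns. The
statistical machinery is standard in the field but rarely available as a
small, tested, reusable library. `oscpls` provides exactly that pipeline:

- **spectral** — short-time Fourier band power (overlapping Hann windows,
  window count fixed per trial, hop derived) in closed task windows;
- **pls** — mean-centered task PLS and behavioural PLS with permutation
  tests on the singular values and Procrustes-aligned bootstrap estimation
  of salience reliability;
- **behaviour** — per-subject summaries, pooled-variance group t tests from
  summary statistics, the first/last-half RT fatigue check, the RT > 1 s
  response-locked trial filter, and the 2.5 SD outlier rule;
- **synthetic** — a generator that emulates the two-group design
  (2 × 16 subjects, 90 virtual channels, 3 bands, 204 trials) with planted
  group × phase effects and a planted brain–behaviour coupling, so every
  downstream stage has a ground-truth recovery test;
- **pipeline / cli** — a reproducible simulate → contrast → PLS → report
  runner (`oscpls simulate|analyze|report|selftest`).

## The statistics

**Task (mean-centered) PLS.** The data matrix `X` stacks participants
within conditions within groups in the rows and channel × band power in the
columns. The group × condition cell-mean matrix `M` is centered on its
grand mean and decomposed, `M_c = U S Vᵀ`. Each latent variable (LV)
comprises a design salience `uᵢ` (the contrast over cells), a brain
salience `vᵢ` (the weighting over channel × band), and a singular value
`σᵢ`; LV i accounts for `100·σᵢ²/Σσⱼ²` percent of the crossblock
covariance. Brain scores are the projections `(X − x̄) v`.

**Inference.** Permutation test: rows are randomly reassigned to cells and
the decomposition recomputed; `p = #{σ_perm ≥ σ_obs}/n_perm`. Bootstrap:
subjects are resampled with replacement within group (all their condition
rows together); each bootstrap SVD is aligned to the original LVs with an
orthogonal Procrustes rotation; per-element standard errors, bootstrap
ratios, and percentile 95 % confidence intervals follow, with an element
"reliable" when its CI excludes zero.

**Behavioural PLS.** Pearson correlations between each behavioural measure
and each brain column are computed within group, stacked group-wise, and
the stacked correlation matrix is decomposed with SVD. Permutations
reassign behaviour to subjects within group; the bootstrap additionally
yields CIs for the per-group correlation between brain scores and each
measure.

## Worked example

```python
from oscpls import (SimulationConfig, generate_power_dataset,
                    build_task_matrix, run_task_pls)
from oscpls.config import config_from_dict

config = config_from_dict({
    "n_per_group": 16, "n_channels": 90, "seed": 1,
    "effects": [{"group": "older", "channels": list(range(30)),
                 "bands": ["theta", "alpha", "beta"],
                 "phase": "test", "magnitude_sd": -1.5}],
})
power, behaviour, truth = generate_power_dataset(config, seed=1)
data = build_task_matrix(power, ["first_study", "test"])
res = run_task_pls(data, n_perm=1000, n_boot=1000, seed=1)
print(f"LV1: {res.crossblock_pct[0]:.1f}% of crossblock covariance, "
      f"perm p = {res.perm_p[0]:.4f}, "
      f"{int(res.boot.reliable[:, 0].sum())} reliable elements")
```

prints

```
LV1: 81.4% of crossblock covariance, perm p = 0.0000, 105 reliable elements
```

i.e. the first latent variable captures the planted older-group test-phase
power decrease (81 % of the crossblock covariance, no permuted singular
value exceeded the observed one in 1000 permutations) and the bootstrap
marks 105 of the 270 channel × band elements as reliably expressing it.

The same analysis from the shell:

```
oscpls analyze --seed 1 --out run1 --n-perm 1000 --n-boot 1000
oscpls report --run run1
```

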