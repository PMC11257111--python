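# Methods

This note records the statistical model behind `neurocross`, the default
parameter choices and why they were made, and the known limitations. All
design decisions described here are the package's own; every numeric claim is
backed by a test in `tests/`.

## 1. Synthetic cohort model

Cross-subject temporal correlation is only meaningful if subjects share a
common underlying process, so the generator plants one:

- **Cohort-shared network courses.** Each of the `N` networks gets one
  unit-variance AR(1) course (`φ = 0.3`) shared by the whole cohort. AR(1)
  gives mild temporal smoothness, like low-pass-filtered resting-state
  signals, while keeping the marginal variance analytically unit.
- **Subject observation noise.** A subject's observed node course is the
  shared course plus independent Gaussian noise of sd 0.3. By the attenuation
  law below, this sets the healthy cross-subject correlation near
  `1/1.09 ≈ 0.92` for pairs of subjects and `1/√1.09 ≈ 0.96` against the
  clean truth — high but not degenerate, as in a well-synchronised healthy
  cohort.
- **Injury as signal replacement.** Injury attenuation `a ∈ [0, 1]` on a
  network replaces the subject's course by
  `√(1−a)·shared + √a·own AR(1)`. The mix keeps unit variance, so injury
  changes *synchrony*, not amplitude — exactly the quantity the cross-group
  statistic measures, and invisible to variance-based checks
  (`tests/test_synth.py` verifies group exchangeability under the null).
- **Optional 4D volumes.** Spatial maps are the smoothed, peak-normalised
  atlas masks; volumes are maps ⊗ courses + voxel noise (sd 0.2), float32.
- **Ground truth is retained** on every record (`truth_ts`), so recovery can
  be scored exactly.

The default grid is 24×24×12 with seven ellipsoidal network masks placed by
rejection sampling under a pairwise overlap cap of 0.2 — a deliberately
downsampled, but still 3-D, stand-in for a template brain. Default series
length is `T = 305` volumes at TR 3 s (a ~15-minute run); the generator
rejects `T < 4N` since shorter series make even the full-correlation netmat
too noisy to be useful.

### Attenuation law (the central oracle)

For a unit-variance signal `x` and noisy copy `x + σε`:

```
corr(x, x + σε) = 1 / √(1 + σ²)
corr(x + σε₁, y + σε₂) = 1 / (1 + σ²)        (x, y shared)
```

The acceptance suite checks the measured cross-diagonal against this curve at
σ ∈ {1, 3, 5, 7, 10, 15} to within 3 standard errors over 200 trials.

## 2. Cross-group statistic

A pseudo-subject stacks one treatment and one control subject's standardized
node series into a `T × 2N` matrix. Its netmat is either:

- **full**: the Pearson correlation matrix, or
- **partial** (default): `−P_ij/√(P_ii P_jj)` with `P = (Σ + ρI)^{-1}`,
  ridge `ρ = 0.1`. With 14 columns and ~300 samples, the unridged inverse is
  usable but noisy; the small ridge stabilises it at negligible bias. At
  `ρ = 0` the estimator equals the precision-matrix closed form to 1e-8
  (acceptance oracle) and the OLS residual-correlation definition of partial
  correlation (property test).

Off-diagonals are Fisher-z transformed with clipping at `±(1 − 1e−7)`, so a
perfect correlation maps to the finite ceiling `Z_MAX ≈ 8.1` instead of
infinity; the identity-groups test pins this ceiling.

The per-node statistic is the cross-block diagonal `M[i, i+N]`.

### Resampling

`resample_cross_group` runs 128 trials. Each trial:

1. drops one subject uniformly from the **pooled** roster (so both groups
   face deletion risk proportional to their size),
2. shuffles both groups independently,
3. pairs subjects positionally up to the smaller group size,
4. averages the per-pair cross-diagonals.

Negative trial averages are rejected at aggregation (negative cross-group
correlation of the same node is treated as non-physiological noise); the
count is reported, and raw trials are retained so users can audit or disable
the rejection. Per-trial random streams come from
`np.random.SeedSequence.spawn`, which makes trial `k` identical whether 16 or
128 trials are requested (prefix stability, tested) and keeps reruns
byte-identical.

## 3. Timepoint inference: why a jackknife

Trials are **not** independent samples: a cohort of 12 has only 12 possible
drop sets and the same subjects appear in every trial. A naive two-sample
t-test on 128 trial values against 128 trial values assumes `n = 256`
independent observations and, in calibration runs during development, flagged
the null in ~90 % of replicates at α = 0.05 — useless.

`compare_timepoints` therefore aggregates trials **by dropped subject**
first: the mean over trials that dropped pooled subject `j` is a delete-one
replicate `θ̂_(j)`, and the jackknife variance

```
v = (n − 1)/n · Σ_j (θ̂_(j) − θ̄)²
```

feeds a two-sample t statistic with Welch–Satterthwaite degrees of freedom.
Measured calibration over 300 null replicates: pooled false-positive rate
0.035 at nominal 0.05 (per-node 0.027–0.047); power 1.0 for a halved injury
attenuation at 6-vs-6 group sizes (see `tests/test_acceptance.py`). The naive
Welch and a one-way ANOVA variant remain available via `test=` for
comparison, and the same reasoning is why reported error bars
(`CrossGroupResult.jackknife_se`, the `stderr` column of the severity table)
are jackknife SEs, not trial-sd/√trials — the latter understates run-to-run
variability by an order of magnitude.

## 4. Node identification

`fit_group_decomposition` concatenates per-subject demeaned volumes in time
and runs either spatial ICA (`FastICA` on the voxels-by-time transpose,
default K = 100) or sparse dictionary learning
(`MiniBatchDictionaryLearning`, default K = 300). Candidate maps are
z-scored, sign-flipped to positive skew, thresholded at z ≥ 1, lightly
smoothed (FWHM 2 voxels), and matched to each binary atlas mask by Pearson
correlation over all voxels (argmax; ties break to the lower component
index). Matching is deliberately correlation-based rather than
overlap-based: it needs no arbitrary binarisation of the candidate map.
`one_to_one=True` switches to a greedy unique assignment. Dual regression
stage 1 (least squares of each volume onto the selected maps) produces
per-subject node series; stage-1-only is sufficient because downstream
analysis needs time courses, not subject-specific maps.

## 5. Severity simulation

A healthy cohort (default 44 subjects) is split 14/14/16 into sham /
simulated-mild / simulated-severe groups. Mild adds Gaussian noise of sd 1 to
three target networks; severe is re-noised *from clean* at each rung of the
ladder (1, 3, 5, 7, 10, 15), so rungs are comparable rather than compounding.
The estimator defaults to full correlation here: with three heavily noised
columns, partial correlation's conditioning adds variance without benefit.
Expected behaviour is the attenuation law; significance stars against the
mild group use the jackknife test of §3.

## 6. CBF spatial analogue

Subjects share one smooth positive baseline perfusion pattern (~50 units,
relative spatial amplitude 0.3, smoothness FWHM 2 voxels), perturbed
multiplicatively per subject (amplitude 0.1). The per-network statistic is
the Fisher-z Pearson correlation between paired subjects' in-mask voxel
vectors, pushed through the *same* pairing generator as the temporal path (a
test asserts the two drop sequences coincide under one seed).

Two modelling points matter:

- **Disruption must break pattern, not just scale.** A uniform hypoperfusion
  factor `f` is invisible to Pearson correlation. The generator therefore
  couples scaling with subject-specific smooth heterogeneity of relative
  amplitude `2·|1 − f|`: stronger hypoperfusion means more disorganised
  flow. This is what makes disruption detectable and recovery testable.
- **The baseline pattern is anatomy.** When generating two sessions of one
  study, pass the same `pattern_seed` so only session noise and group effects
  differ between timepoints; independent patterns would make *every* network
  appear to change.

## 7. Numerical and I/O choices

- All randomness flows through `numpy.random.SeedSequence`; user-facing seeds
  are plain ints below 2³¹, and every CLI run writes its full configuration
  to a JSON sidecar.
- Tables are UTF-8 TSV with one leading `#` units comment, written atomically
  (tmp + rename); volumes are NIfTI via nibabel; 4D data is stored float32.
- Netmats symmetrise `(M + Mᵀ)/2` before Fisher transform to remove
  float-asymmetry of the inverse.
- Near-singular correlation matrices (condition number > 1e12) raise an
  error that suggests the ridge rather than silently returning noise.

## 8. Limitations

- The generator's networks are spatially compact ellipsoids with box-car
  masks; real RSNs are distributed and overlapping. Node *selection* results
  transfer only qualitatively.
- AR(1) courses have no spectral structure, scanner drift, or motion;
  preprocessing robustness is out of scope.
- The jackknife test treats the dropped-subject replicates as exchangeable;
  with very small groups (< 4 per group) its degrees of freedom are few and
  power drops sharply.
- Negative-trial rejection is a one-sided physiological prior; for signed
  hypotheses, work from `CrossGroupResult.trials` directly.
- CBF detectability depends on the disruption-heterogeneity coupling; a
  purely uniform perfusion deficit is undetectable by design of the Pearson
  statistic, not by a fixable flaw in the implementation.
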