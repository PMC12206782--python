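# Methods

## Data model

A gait record is a stride-indexed table in the gaitndd 13-column layout:
elapsed time (s) followed by 12 interval series — left/right stride,
swing and stance in seconds and as % of stride, plus double support in
seconds and % of stride. Percent series stay on the 0–100 scale; no unit
conversion is applied anywhere. A record is *invalid* iff any interval is
≤ 0; negative intervals are the database's marker for corrupt strides,
and exclusion is a caller-level decision so the full cohort can still be
inventoried (the validator reports findings; the pipeline excludes
records with `negative_value` findings before statistics).

## Preprocessing

1. **Start-up trim.** Strides with elapsed time < `startup_trim`
   (default 20 s) are dropped from every series consistently. The
   recording protocol starts with the subject stationary, and the first
   strides are unstable; 20 s is the conventional settle-in allowance
   for 5-minute corridor walks. Configurable.
2. **Ratio transform.** For each of the five left/right pairs (stride s,
   swing s, swing %, stance s, stance %), q(i) = L(i)/R(i) over the
   aligned pairs; pairs with a non-positive member are dropped and
   counted. By default ratios are taken on unfiltered series and the
   median filter is applied afterwards (ratio-then-filter); a
   `filter_before_ratio` switch reverses the order.
3. **Median filter.** Width n = 2k+1 (odd, default 3: the width at which
   spike suppression is strongest without flattening structure), with
   edge replication: the first value repeated k times before the series,
   the last k times after, so output length equals input length. The
   filter removes isolated turn spikes exactly (a single outlier never
   survives a width-3 median) while leaving monotone trends untouched.
4. **Outlier deletion** (median ± 3·SD) exists as an optional rule for
   group statistics only; feature extraction relies on the median filter,
   not deletion.

## Features

All features are computed per series after trimming and (by default)
median filtering; series shorter than 16 strides are skipped with a
recorded reason. Features cover the 10 single-side series and the 5
ratio series (double support has no left/right contrast).

- **C0 complexity.** The DFT bins whose squared magnitude exceeds
  r × the mean squared magnitude are kept (default r = 5); the inverse
  transform of the kept spectrum is the regular part x̃;
  C0 = Σ|x−x̃|²/Σ|x|². Magnitude thresholding preserves conjugate
  symmetry, so x̃ is real. C0 is clipped to [0, 1] against floating-point
  residue, is 0 for constants and pure tones, near 1 for broadband
  noise, and is nondecreasing in r (a larger threshold keeps fewer
  bins, so the residual can only grow).
- **Sample entropy.** Chebyshev distance, self-matches excluded, B
  computed over the first N−m templates of length m and A over the N−m
  templates of length m+1, −ln(A/B); ∞ is returned when no m+1 match
  exists. Defaults m = 2 and r = 0.2·SD of the (filtered) series — the
  field-standard parameterisation. The implementation is vectorised but
  exact; tests pin it to an exhaustive O(N²) pair-count oracle.
- **Wavelet entropy and coefficient summary.** Multilevel DWT (db4,
  depth min(4, maximum for the length)) in periodization mode, which
  keeps coefficient counts dyadic and the transform orthogonal, so band
  energies account for the signal energy exactly. Band energies are the
  summed squared detail coefficients per level plus the final
  approximation as one band; entropy is −Σ pⱼ ln pⱼ (natural log;
  0·ln 0 = 0), with an optional ln J normalisation switch. The
  coefficient summary is detail-RMS over signal-RMS: dimensionless,
  scale-invariant, 0 for constants. It is one defensible scalarisation
  of the detail expansion and is labelled as such in outputs.

## Group statistics

Per-subject statistics (mean, sample SD with n−1, CV = 100·SD/mean) are
aggregated with equal subject weighting by default — the group mean of
per-subject means — with a pooled, stride-count-weighted variant behind
a flag; outputs label which variant produced them. Groups are compared
with the tie-corrected Kruskal–Wallis H (chi-square p, k−1 df; H = 0 and
p = 1 when all pooled observations are identical) and ranked by
descending group mean with lexicographic, flagged tie-breaks. No
multiple-testing correction is applied across the 15 series kinds.

## Synthetic cohort generator

The generator emulates the gaitndd cohort: 13 ALS, 15 PD, 20 HD and 16
control subjects, 5-minute walks. Per subject:

- left stride = subject mean + stationary AR(1) fluctuation, truncated
  at 0.3 s; subject means are Gaussian about the group mean;
- right stride = left / (subject asymmetry ratio) + independent
  Gaussian noise, so the ratio series is centred on the asymmetry with
  a white within-subject fluctuation;
- swing = fraction·stride + noise clipped inside (0, stride); stance is
  the exact complement (stride is stored as the literal float sum
  swing + stance so the additivity identity is bit-exact); percent
  series are exactly 100·phase/stride;
- corridor turns: with probability 0.02 per stride both sides' stride is
  doubled (turn_scale = 2), giving the sparse large spikes the median
  filter is there to remove;
- elapsed time is the cumulative left-stride sum. Everything is
  reproducible from a single seed via spawned generator streams.

Calibration (defaults in `data/group_presets.csv`): group stride means,
asymmetry ratios and swing fractions are the published gaitndd group
statistics (e.g. ALS 1.3911 s, asymmetry 1.0177; control 1.0932 s,
0.9969). Published group SDs pool within- and between-subject spread;
the generator splits them, taking within-subject SDs from the published
detrended stride SDs (control 0.027 s … HD 0.120 s) and between-subject
jitter as the quadrature remainder. The ratio SD is likewise split
70%/70% between between-subject asymmetry jitter and within-subject
left–right noise; the true split is unpublished, making the cross-noise
magnitude a free parameter chosen once here. The AR(1) coefficients
(control 0.88, PD 0.75, HD 0.60, ALS 0.05) encode the published group
ordering of gait irregularity — entropy and complexity decreasing
ALS > HD > PD > control: sample entropy at relative tolerance is
amplitude-invariant, so ordering must come from temporal structure, and
a width-3 median prefilter erases AR(1) contrasts narrower than these.
Control and PD values match lag-1 coefficients typical of real stride
series; HD and ALS are set lower than their measured autocorrelation
would suggest, a deliberate choice to make the generator's presets carry
the target feature ordering.

What the generator does **not** emulate: non-stationary drift, the
actual spectral shape of pathological gait beyond AR(1), gap structure
from turns (turn strides are inflated, not missing), real double-support
mechanics (modelled as stance_L + stance_R − stride, floored at 0.01 s),
and any left–right correlation structure beyond the ratio mean and white
cross-noise. Passing tests therefore demonstrate pipeline correctness
and sensitivity to the calibrated contrasts, not clinical validity on
real recordings.

## Numerical choices and degenerate inputs

- Median filter: even widths rejected; n = 1 is the identity.
- C0: all-zero input rejected (zero denominator); value clipped to
  [0, 1].
- SampEn: requires N > m + 1; returns ∞ when A = 0; constant input
  gives 0 (A = B).
- Wavelet features: depth exceeding the maximum for the length is an
  error in the low-level API and capped in `extract_all`; zero-energy
  input rejected.
- Ratio: all-pairs-dropped is an error; element counts are tracked.
- Determinism: cohort generation, feature extraction and summaries are
  byte-reproducible for a fixed seed.

## Problem sizes

Default tests and the acceptance script run on full-size synthetic
cohorts (64 subjects, ~200–270 strides per subject, i.e. 5-minute
walks); oracle-equivalence tests use series up to N = 200 (sample
entropy) and 1,000 random sequences (median filter); ordering checks
use 10 seeded cohorts for C0 and 3 for sample entropy, sizes at which
the calibrated contrasts dominate sampling noise.

## Known limitations

- The scalar "wavelet coefficient" feature is one reading of an
  under-determined summary; outputs label it `wavelet_coeff` and the
  definition (detail-RMS / signal-RMS) is fixed and documented.
- C0's regular-part construction (threshold at r × mean power) is the
  standard one; other constructions (fixed bin counts, iterative
  thresholds) would shift absolute values, though not the group
  ordering the pipeline relies on.
- Group summaries on real data depend on whether series were trimmed/
  filtered first; the feature CSV carries provenance columns
  (`prefiltered`, `filter_n`, `startup_trim_s`) so every summary can be
  traced to its variant.
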