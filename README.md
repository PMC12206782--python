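# gaitnld

Nonlinear analysis of stride-interval gait signals in neurodegenerative
disease.

Gait records from patients with amyotrophic lateral sclerosis (ALS),
Parkinson's disease (PD) and Huntington's disease (HD) differ from healthy
controls in stride-to-stride variability and in left/right asymmetry, but
raw left- and right-limb interval series are widely dispersed across
subjects (age, height, speed), which blurs group differences. This package
implements a pipeline built around the **left-to-right ratio transform**:
for each paired interval series (stride, swing, stance; seconds and % of
stride) it forms the element-wise quotient

    q(i) = L(i) / R(i),        q ≡ 1 ⇔ perfect symmetry,

which cancels subject-level scale and isolates asymmetry and its
fluctuation. Ratio and raw series are denoised with a width-3 running
median (edge-replicated windows) and characterised by four nonlinear
features:

- **C0 complexity** — split the signal x(t) into a spectrally "regular"
  part x̃(t) (DFT bins whose power exceeds r × the mean bin power, r = 5)
  and report the residual energy fraction
  `C0 = Σ|x−x̃|² / Σ|x|²` ∈ [0, 1];
- **sample entropy** — `SampEn(m, r) = −ln(A/B)`, the conditional
  probability that length-m template matches (Chebyshev distance ≤ r,
  self-matches excluded) persist at length m + 1; defaults m = 2,
  r = 0.2·SD;
- **wavelet entropy** — Shannon entropy `−Σ pⱼ ln pⱼ` of the relative
  band energies of a multilevel db4 wavelet decomposition;
- **wavelet-coefficient summary** — RMS of all detail coefficients over
  the RMS of the signal.

Per-subject features are aggregated into group tables
(mean ± SD, CV = 100·SD/mean), compared with tie-corrected
Kruskal–Wallis tests, and ranked. A calibrated synthetic-cohort generator
(13 ALS, 15 PD, 20 HD, 16 control subjects; 5-minute walks with corridor-
turn artifacts, AR(1) stride dynamics and group-specific asymmetry)
reproduces the statistical structure of the public *gaitndd* database so
that the full pipeline is testable without downloading it. Records use
the gaitndd 13-column whitespace layout (elapsed time + 12 interval
series); corrupt records (negative intervals) are detected and excluded
the way the database's known bad HD record is.

## Worked example

```python
import numpy as np
from gaitnld import (SimConfig, generate_cohort, lr_ratio, median_filter,
                     c0_complexity, sample_entropy,
                     SeriesKind, Side, Phase, Unit)

cohort = generate_cohort(SimConfig(seed=42))          # 64 subjects
rec = cohort[0]
left  = rec.series[SeriesKind(Side.LEFT,  Phase.STRIDE, Unit.SECONDS)]
right = rec.series[SeriesKind(Side.RIGHT, Phase.STRIDE, Unit.SECONDS)]
print(f"{rec.subject_id} ({rec.group.value}): {rec.n_strides} strides")
print(f"left stride mean  : {left.mean():.4f} s")
ratio = lr_ratio(left, right)
print(f"stride ratio mean : {ratio.values.mean():.4f} (pairs used {ratio.n_pairs_used})")
smooth = median_filter(ratio.values, 3)
print(f"C0 complexity     : {c0_complexity(smooth):.6f}")
print(f"sample entropy    : {sample_entropy(median_filter(left, 3)):.4f}")
```

prints

```
als1 (ALS): 216 strides
left stride mean  : 1.5225 s
stride ratio mean : 1.0310 (pairs used 216)
C0 complexity     : 0.000254
sample entropy    : 0.7230
```

This ALS subject walks with slow strides (1.52 s), a 3% left/right
asymmetry, and a ratio series whose C0 is two orders of magnitude above
a control's (~1e-6): the asymmetry fluctuation, not the raw stride
variance, is what separates the groups.

The same analysis is scriptable end to end:

```sh
gaitnld simulate --seed 42 --out data/
gaitnld features data/ --out features.csv
gaitnld summarize features.csv --out tables/
```

`tables/` then holds the per-group summary tables (gait statistics, C0,
sample entropy, wavelet entropy, wavelet coefficients), the
Kruskal–Wallis tests and the group rankings, each recomputable from
`features.csv`.

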