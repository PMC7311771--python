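# mmspike

Stochastic-signature analysis of involuntary head motion for movement
neuroscience and autism research. Starting from the six rigid-body
realignment parameters that fMRI volume registration saves for every scan
(three rotations in degrees, three translations in mm), the package
quantifies how noisy and how predictable a person's involuntary head
micro-motions are, and compares those signatures across age groups and
between autistic (ASD) and typically developing (TD) cohorts.

## What it computes

1. **Speed waveforms.** Framewise linear speed ‖Δ**x**‖/Δt (mm/s) and
   angular speed ‖Δ**θ**‖/Δt (deg/s), plus cumulative head excursions
   (path length of displacement and rotation over the scan).
2. **Micro-movement spikes (MMS).** Every local speed peak p is
   renormalized as

   &nbsp;&nbsp;&nbsp;&nbsp;A = p / (p + m),

   with m the mean of the waveform over the trough-to-trough window around
   the peak. A ∈ (0, 1] is invariant to multiplying the waveform by any
   constant, removing anatomical-size (allometric) differences between
   children and adults.
3. **Gamma signatures.** Pooled MMS amplitudes are fitted by maximum
   likelihood against Gaussian, Lognormal, Exponential and Gamma families;
   the Gamma fit gives shape a and scale b with 95% CIs, the moments
   (mean ab, variance ab², skewness 2/√a, kurtosis 3 + 6/a), and the
   **noise-to-signal ratio** NSR = b = variance/mean. Shape → 1 marks the
   memoryless Exponential regime; large shape tends Gaussian.
4. **Bootstrap ensembles.** Each (age bin × diagnosis) cell yields 100
   random subgroups of 25 subjects; each subgroup's pooled amplitudes give
   one signature, producing 100 comparison units per cell regardless of the
   cell's raw size.
5. **Group comparison.** Pairwise Kruskal–Wallis and Kolmogorov–Smirnov
   p-value matrices (within TD, within ASD, TD vs ASD; * p < 0.05,
   ** p < 0.01, uncorrected), Welch t-tests on excursions, and Cohen's d /
   Glass's Δ effect sizes with magnitude labels (0.8 large, 2.0 huge).

A synthetic-cohort generator with known ground-truth Gamma structure stands
in for repository data, so the whole chain is testable offline.

## Worked example

```python
import numpy as np
from mmspike import extract_mms, select_best_family
from mmspike.kinematics import SpeedSeries

speed = SpeedSeries("demo", "linear", 1.0, np.array([1.0, 3, 1, 5, 1]))
train = extract_mms(speed)
print(train.amplitudes)          # [0.64285714 0.68181818]
```

The two peaks (3 and 5) are normalized over their trough-to-trough windows:
3/(3 + 5/3) = 9/14 ≈ 0.6429 and 5/(5 + 7/3) = 15/22 ≈ 0.6818. Scaling the
series by any constant leaves these numbers unchanged.

```python
rng = np.random.default_rng(0)
sig = select_best_family(rng.gamma(2.0, 0.05, size=5000))
print(round(sig.shape, 3), round(sig.nsr, 4), sig.best_family)
# 1.987 0.0511 gamma
```

The fitted shape/scale recover the generating law (2.0, 0.05); the NSR is
the scale.

## Analysis scripts

The `analysis/` drivers run the full study on a synthetic cohort:

```sh
python analysis/01_generate_cohort.py --seed 0       # 14 cells x 30 subjects
python analysis/02_run_pipeline.py   --seed 0        # signatures + matrices
python analysis/03_report.py                         # star-annotated report
python analysis/04_noise_contrast_stability.py       # repeated-draw stability
```

With seed 0 the run prints, among others, the ensemble-mean NSR per cell
(linear speed) — ASD rows above TD rows in every age bin:

```
age_bin      11-15    16-20    21-25    26-30    31-40    41-65     5-10
ASD        0.00539  0.00524  0.00544  0.00520  0.00517  0.00500  0.00563
TD         0.00499  0.00452  0.00475  0.00437  0.00413  0.00435  0.00444
```

and excursion effect sizes in the very-large-to-huge range (e.g. 5–10 yo
linear: Cohen d = 2.01, Glass Δ = 2.97, t-test p = 7e-10). The same steps
are available as a CLI: `mmspike generate|run|report`.

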