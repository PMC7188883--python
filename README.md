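# tiltadapt

Analysis pipeline for **gradual visuomotor-rotation adaptation** experiments
run on tilt-controlled smart devices, with a full synthetic-cohort simulator
for validation and parameter-recovery studies.

## The scientific problem

In a visuomotor-rotation paradigm a participant steers a cursor toward a
target — here by tilting a tablet — while the mapping from movement to cursor
is rotated by an angle p_t that changes **gradually** (±1°/trial, up to ±15°,
in 40-trial clockwise and counterclockwise blocks). Because the perturbation
is too small to notice, compensation is implicit motor adaptation rather
than a cognitive re-aiming strategy. The scientific questions are *how
strongly*, *how faithfully* and *with what lag* a participant's reach angles
track the perturbation schedule — questions asked, for example, when
comparing medicated Parkinson's-disease (PD) patients against elderly and
young controls, where the clinically interesting pattern is a **larger but
not better** adaptive response in PD.

This package implements that analysis end to end:

- **Device model** — the tablet's tilt-to-cursor mapping: per axis a
  first-order low-pass filter `p ← 0.95·p + 0.05·arcsin(a) − o` (arcsin in
  degrees, accelerometer reading `a`, offset `o`), then a clockwise-positive
  rotation of the filtered tilt vector by p_t; triangular perturbation
  schedules and session layouts (20 practice + 80 adaptation trials).
- **Kinematic scoring** — per trial: movement onset (display y-velocity
  exceeding the trial mean + 2.5 SD), the frame of peak y-velocity, the
  signed movement angle between target line and velocity there, the
  adaptation effect `e_t = p_t − angle` (0 = no compensation, p_t = full),
  movement time, and lateral trajectory error; outlier exclusion when the
  effect exceeds `±(c + p_t)` (default c = 15°); CW/CCW averaging with the
  CCW sign flipped and single-block substitution into a 40-entry
  **adaptation curve** x = (x_1 … x_40).
- **Decomposition** — against the schedule fragment p = (p_9 … p_32):

      Δ* = argmin_Δ (1/24) Σ_{j=9}^{32} (x_{j+Δ} − p_j)²   (Δ ∈ 0..8)
      A  = |x(Δ*)| / |p|
      φ  = arccos[ x(Δ*)·p / (|x(Δ*)||p|) ]
      RMSE = sqrt( (1/24) Σ (x_{j+Δ*} − p_j)² )

  i.e. temporal delay, amplitude, phase and residual error of the response.
- **Group statistics** — per-trial one-sample t-tests vs 0 with Bonferroni
  correction to locate the significant-adaptation window; one-way ANOVA with
  Tukey HSD across groups; pooled-variance two-sample t-tests (also from
  published summary statistics); Pearson/Spearman correlations; within-group
  z-scoring of movement times.
- **Synthetic cohorts** — delayed-gain subjects
  `e*_t = A_true · p_{t−Δtrue} + N(0, σ²)` whose 200-Hz trial logs are
  generated through the *inverse* device model, so the full pipeline can be
  validated closed-loop (generation → scoring → decomposition recovers the
  generating parameters). Group presets follow the reported PD / elderly /
  young cohort summaries (amplitude 0.91/0.75/0.72, delay 3/4/5 trials,
  movement time 109/96/51 ms), with Table-style demographics.

## Worked example

```python
from tiltadapt.pipeline import run_pipeline

result = run_pipeline({"cohort": {"n_per_group": 6}}, seed=11, out_dir="demo")
print(open("demo/report.txt").read())
```

prints (abridged):

```
tiltadapt report (seed 11, hash aec9d604407e1fcd)
significant window (corrected p < 0.01): trials 8-28
amplitude: F(2,15) = 247.500, p = 3.265e-12 | PD 0.912+-0.004, elderly 0.789+-0.005, young 0.735+-0.008 | PD vs elderly: p=0.0000; PD vs young: p=0.0000; elderly vs young: p=0.0000
delay: F(2,15) = 30.278, p = 5.416e-06 | PD 2.833+-0.167, elderly 3.667+-0.211, young 4.833+-0.167 | ...
movement_time_ms: F(2,15) = 1695.723, p = 2.13e-18 | PD 94.638+-0.297, elderly 88.763+-0.421, young 62.633+-0.498 | ...
  amplitude vs normalized_movement_time: r=0.124 (p=0.625), rho=0.255 (p=0.307)
```

Reading it: the simulated PD group's adaptation curves track the rotation
schedule with the largest amplitude (0.912, close to its generating value
0.91) and the shortest delay (~3 trials), the adaptation effects are
significantly non-zero over a contiguous mid-block trial window, and the
movement-time differences do not correlate with amplitude once movement time
is normalized within group — the same qualitative pattern the method is
designed to resolve. The six-per-group demo keeps the example fast; at the
full cohort size (18 per group) amplitudes recover to within ±0.03 of the
generating values.

A command-line interface mirrors the stages:

```bash
tiltadapt simulate --group PD --group young --n 4 --seed 1 --out sim/
tiltadapt extract sim/trial_logs.csv --out scored/
tiltadapt decompose scored/curves.csv --out decomposition.csv
tiltadapt run --seed 1 --out full_run/      # simulate + analyze in one step
```

## Layout

- `src/tiltadapt/device.py` — filter, rotation, schedules, session plans
- `src/tiltadapt/simulate.py` — synthetic subjects, trials and cohorts
- `src/tiltadapt/kinematics.py` — trial scoring, exclusion, adaptation curves
- `src/tiltadapt/decomposition.py` — delay / amplitude / phase / RMSE
- `src/tiltadapt/stats.py` — windows, ANOVA + Tukey, t-tests, correlations
- `src/tiltadapt/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
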