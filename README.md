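# cispop

Condition-invariant signal analysis for motor-cortex population recordings.

## The problem

During a delayed reach, motor and premotor cortex neurons are tuned: their
firing rates depend on which reach is being prepared.  Yet when the
population response is decomposed into shared *components* — patterns
`x_{i,c,t}` over conditions `c` and time `t` from which each neuron's rate
is composed as a weighted sum,

```
r_{n,c,t} = Σ_i  w_{n,i} · x_{i,c,t}
```

— the largest component turns out to be **condition-invariant**: its time
course is nearly identical for every reach, and it rises abruptly about
150 ms before movement onset.  This condition-invariant signal (CIS)
carries timing ("when to move"), not movement identity ("which move"), and
the latency of its rise predicts reaction time on single trials.

`cispop` implements the full population-analysis machinery needed to
establish such a claim, together with a synthetic-data generator that
plants known ground truth, so every stage is testable without access to
recordings:

- **`cispop.synthgen`** — delayed-reach population generator: planted CIS
  (sigmoidal rise 150 ms before movement), preparatory tuning, ~2 Hz
  rotational components, per-trial latency jitter, inhomogeneous-Poisson
  spiking, a condition-correlated muscle-like population, and the analytic
  `g_c sin(t)` / `h_c sin(3t)` counterexample.
- **`cispop.preprocess`** — Gaussian spike smoothing (28 ms SD), dual
  alignment (target onset / movement onset), trial averaging, SNR
  screening, soft normalization (range + 5 spikes/s), and assembly of the
  labeled analysis matrix `R`.
- **`cispop.demix`** — demixed decomposition into orthonormal
  condition-invariant vs condition-specific dimensions via greedy
  marginalization eigenvectors; marginal-variance accounting; the >50%
  classification rule; dimensionality selection (smallest `D` giving eight
  condition-specific components); PCA comparison; and an exact feasibility
  analysis (generalized eigenproblem) answering whether *any* linear
  combination of known components is condition-invariant, with the
  `(C−1)·T > D` counting rule.
- **`cispop.controls`** — three surrogate controls: frequency-matched
  phase-randomized PSTHs, CIS-removal + rectification, and
  condition-correlated contamination, plus a repetition harness.
- **`cispop.rtpredict`** — single-trial RT prediction by criterion
  crossing (midpoint of the median long-delay trace), comparison of five
  dimension-finding methods, a premovement/movement logistic classifier
  with per-component influence, and speed decoding.
- **`cispop.statespace`** — rotational-plane identification by
  skew-symmetric least squares on the condition-specific components, the
  CIS + rotation 3-D projection, and neural-speed timing comparison.

## Worked example

```python
from cispop import PipelineConfig, GeneratorConfig, run_pipeline

config = PipelineConfig(
    generator=GeneratorConfig(seed=1, trial_counts={0.0: 8, 500.0: 30}),
    out_dir="demo_out", control_reps=2,
)
report = run_pipeline(config)
```

which prints/stores (abridged):

```json
{
  "dimensions": 10,
  "n_ci_components": 2,
  "max_f_ci": 0.992,
  "dpca_vs_pca_variance_ratio": 0.9996,
  "first_dim_angle_deg": 1.63,
  "control_max_f_ci": {
    "add_condition_correlated": 0.309,
    "phase_randomize": 0.039,
    "remove_cis_rectify": 0.288
  },
  "rt_r_by_delay": {"500.0": 0.955},
  "rotation_frequency_hz": 1.92,
  "cis_lead_ms": 180.0
}
```

Reading the numbers: requesting dimensions until eight are
condition-specific yields `D = 10` with two condition-invariant
components; the largest carries 99% condition-invariant variance
(`max_f_ci`), and the demixed dimensions capture 99.96% as much variance
as the same number of principal components, with the leading dimensions of
the two methods only 1.6° apart — the CIS is real structure, not an
artifact of the method.  All three surrogate controls destroy it (maximum
condition-invariant fraction 0.04–0.31, i.e. every surrogate component is
classified condition-specific).  The criterion-crossing time of the CIS_1
projection correlates with single-trial RT at r = 0.96, the planted 2 Hz
rotation is recovered at 1.92 Hz, and the peak rate of change in the CIS
dimensions leads the rotational plane by 180 ms.

The same stages are scriptable from a shell (`cispop simulate`,
`cispop demix`, `cispop controls`, `cispop rtpredict`, `cispop statespace`,
`cispop report`); see `cispop --help`.

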