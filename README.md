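# switchssm

Variational Bayesian inference and learning for **switching linear-Gaussian
state-space models**, with classical comparators and an unsupervised
**sleep-spindle detector** built from switching oscillator models.

## The problem

Neural time series (EEG above all) are rarely stationary: transient events —
sleep spindles, bursts, rapid changes in coupling — live on top of slowly
varying background dynamics. A switching state-space model represents such a
signal with a pool of `M` linear-Gaussian state-space models

```
x_t^(m) = F^(m) x_{t-1}^(m) + w_t^(m),   w ~ N(0, Q^(m))
y_t     = G^(s_t) x_t^(s_t) + v_t,       v ~ N(0, R)
```

whose hidden states evolve in parallel, while a hidden Markov chain
`s_t ∈ {1..M}` (initial probabilities `ρ`, transition matrix `φ`) selects
which model emits each observation. Exact posterior inference is intractable
(the cost grows exponentially in `T`), so this package implements a
structured variational approximation: the posterior over the chain and the
posterior over the Gaussian states are coupled only through two per-time,
per-model statistics —

* `g_t(m)`, the **model evidence**, a surrogate log emission probability fed
  to the HMM forward–backward recursion, and
* `h_t(m)`, the **model responsibility**, which rescales the observation
  noise of model `m` to `R / h_t(m)` during Kalman/RTS smoothing,

iterated to a local maximum of the negative variational free energy
`F(q, θ) ≤ log p(y | θ)`. Because the free-energy landscape is riddled with
local maxima, initialization decides everything; the package provides

* **interpolated-density initialization (VI-I)** — initialize `g_t(m)` with
  the exact leave-one-out predictive densities
  `log p^(m)(y_t | y_1..t-1, y_t+1..T)`, computed in O(T) by a two-filter
  (forward Kalman + backward information) construction, and
* **deterministic annealing (VI-A)** — temperature-scaled updates with the
  schedule `T_{i+1} = (T_i + 1)/2` from `T_0 = 100`.

A generalized EM loop (`vbem`) wraps the E-step with closed-form M-step
updates for all parameters, including **tied parameters** shared across
candidate models (element-masked transition matrices, pooled state noise,
shared oscillator blocks, shared `R`). Classical baselines — static
per-time Bayes, the interacting-multiple-models (IMM) filter and the
Shumway–Stoffer observation-switched merging filter — are included for
comparison.

## Worked example

Two AR(1) models (`F=0.99, Q=1` vs `F=0.90, Q=10`, `R=0.1`) switched by a
sticky binary chain (`φ_diag = 0.95`):

```python
import switchssm as sw

model = sw.make_ar1_switching()
sim = sw.simulate(model, T=200, seed=1)          # y, true switch path
res = sw.fixed_point_estep(model, sim.y,
                           sw.EStepConfig(init_mode="interpolated", max_iter=12))
acc = sw.segmentation_accuracy(res.varstate.h, sim.s)
print(f"accuracy {acc:.3f}, free energy {res.varstate.free_energy:.1f}")
```

prints (seed 1):

```
accuracy 0.910, free energy -542.5
```

`res.varstate.h` holds the posterior probability that each model generated
each sample (rows sum to one; thresholded at 0.5 for the accuracy), and the
free energy is the variational lower bound on `log p(y)` at the fixed point.
Across 200 such sequences the mean accuracies are ≈ 0.89 (VI-I), 0.87 (IMM),
0.81 (static), 0.80 (VI-A) — see the benchmarks below.

Spindle detection on a synthetic sleep-EEG record:

```python
from switchssm.spindle import synthesize_sleep_eeg, RunConfig
import switchssm as sw

y, truth = synthesize_sleep_eeg(duration_s=30.0, seed=42)   # 1 Hz slow + 13 Hz spindles
events, probs, waves, fitted = sw.detect_spindles(y, 100.0, RunConfig())
for e in events:
    print(f"{e.onset_s:6.2f}-{e.offset_s:6.2f} s  p={e.peak_probability:.2f}  "
          f"f={e.center_freq_hz:.1f} Hz")
```

prints (seed 42):

```
  3.53-  3.86 s  p=1.00  f=13.2 Hz
  4.22-  5.88 s  p=1.00  f=13.2 Hz
 10.52- 12.01 s  p=1.00  f=13.2 Hz
 17.51- 20.26 s  p=1.00  f=13.2 Hz
 20.57- 23.55 s  p=1.00  f=13.2 Hz
```

recovering every injected spindle (the first burst is split by a brief
probability dip) with the learned centre frequency within 0.2 Hz of the
generator's 13 Hz.

## Command line

```bash
switchssm simulate --model spindle --duration 30 --seed 1 --out sim
switchssm detect-spindles sim_series.csv --fs 100 --out-prefix spindles
switchssm benchmark ar1_inference --reps 200 --seed 1
switchssm fit / switchssm infer    # model fitting and posterior inference
```

Outputs are CSV/JSON at fixed float precision (identical config + seed gives
byte-identical files).

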