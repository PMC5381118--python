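# oxydyn

Oxygen-uptake (V̇O₂) prediction from wearable-sensor streams, and
frequency-domain assessment of aerobic temporal dynamics, for exercise
physiologists and wearable-health researchers.

Directly measuring V̇O₂ requires a metabolic cart, which confines aerobic
assessment to the laboratory. `oxydyn` implements the full alternative
pipeline: wearable channels — heart rate (HR) and its 1-s lagged difference
ΔHR, minute ventilation (V̇E), breathing frequency (BF), hip acceleration
(H_acc) and walking cadence (CAD) — are synchronised to 1 Hz, low-pass
filtered at 0.01 Hz, and fed to a bagged regression-tree forest that predicts
V̇O₂ (ml·min⁻¹·kg⁻¹). The forest is validated by leave-one-participant-out
cross-validation, and the predicted V̇O₂ is then good enough not only for
intensity (METS) classification but for *system identification*: estimating
how fast a person's aerobic system responds to changing demand.

## The core method

**Regression forest.** Each tree grows by recursive binary splitting. At a
node, candidate splits over feature *x_i* and threshold *s* minimise the sum
of squared residuals

    SSR(s, x_i) = Σ_{x_i ≤ s} (y − ȳ_L)² + Σ_{x_i > s} (y − ȳ_R)²,

with the winning feature chosen by argmin over a random ⅓ subset of the
features; a leaf predicts the mean in-bag target reaching it, and the forest
prediction is the bag's weighted average of tree predictions. One forest is
trained per cross-validation fold (held-out participant); their unweighted
average is the final predictor.

**PRTS protocol.** Walking cadence follows a pseudorandom ternary sequence:
a maximal-length GF(3) m-sequence (26 symbols × 30 s = 780-s period, levels
75/105/135 steps·min⁻¹, 300-s warm-up). With the antisymmetric symbol
mapping, even harmonics of the period carry exactly zero stimulus, so the
aerobic system is probed at the odd harmonics f_k = k/780 Hz, k ∈ {1, 3, 5}
(≤ 0.008 Hz, the band where V̇O₂ behaves as a linear first-order system).

**Mean normalised gain (MNG).** With H_acc as input and V̇O₂ as output, both
averaged over the two PRTS repeats, harmonic gains G_k = |Y(f_k)|/|X(f_k)|
are normalised by the first-harmonic gain, g_k = G_k/G_1, and

    MNG = 100 × mean_k g_k   (percent).

For a first-order system with time constant τ,
g_k = √((1 + (2πf₁τ)²)/(1 + (2πf_kτ)²)), so MNG decreases monotonically in
τ: higher MNG = faster aerobic response. Normalisation removes the static
gain, so MNG is invariant to units and fitness-unrelated scaling.

Because no public recordings accompany this problem, the package ships a
first-class synthetic cohort generator: participants with known first-order
kinetics (τ ∈ [20, 60] s), breath-by-breath sampling jitter and Gaussian
sensor noise, walking the full protocol (rest, PRTS, activities of daily
living, PRTS). The closed-form MNG(τ) is the oracle the whole pipeline is
verified against.

## Worked example

```python
from oxydyn import (RunConfig, run_study, default_schedule,
                    stimulated_harmonics, first_order_mng_closed_form)

sched = default_schedule()
h = stimulated_harmonics(sched)
print(sched.period, h.indices)                       # 780.0 (1, 3, 5)
print(first_order_mng_closed_form(30.0, h))          # 82.96

cfg = RunConfig.model_validate({
    "seed": 42,
    "sim": {"n_participants": 4},
    "forest": {"n_trees": 10, "min_leaf": 20, "train_stride": 2},
})
bundle = run_study(cfg)
rep = bundle.report
print(f"ADL  r = {rep.adl_pooled.r:.3f}, bias = {rep.adl_pooled.bias:+.3f}")
print(rep.mng_table[["participant_id", "mng_measured_pct", "mng_predicted_pct"]])
```

Output:

```
ADL  r = 0.985, bias = -0.087 ml/min/kg
participant_id  mng_measured_pct  mng_predicted_pct
           P00             73.31              68.84
           P01             78.37              81.52
           P02             87.41              83.33
           P03             73.89              72.71
```

The ADL line says held-out V̇O₂ predictions track the measured signal during
activities of daily living almost perfectly (r = 0.985) with a bias under
0.1 ml·min⁻¹·kg⁻¹. The MNG table compares the aerobic-dynamics index
computed from measured vs predicted V̇O₂; both rank the participants'
generative time constants correctly (P02, τ ≈ 23 s, is the "fittest";
its true closed-form MNG is 87.94 %).

The same pipeline is scriptable from the shell:

```sh
oxydyn simulate --n 16 --seed 7 --out data/
oxydyn train    --data data/ --out model.json
oxydyn report   --data data/ --model model.json --out report.json
oxydyn run-all  --seed 7 --out bundle/          # everything in one step
```

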