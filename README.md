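# acticam

Classify a driver's recent **sitting history** and **sleep history** from
raw thigh-worn accelerometry recorded during short simulated drives, and
explain the classifications with **class activation maps (CAM)**.

Prolonged sitting and inadequate sleep both impair the psychomotor skills
driving depends on. A thigh-worn triaxial accelerometer captures the leg
movements a driver makes at the pedals — and, through the way the 1 g
gravity vector projects onto the device axes, the thigh's posture. This
package implements the full analysis pipeline that turns such recordings
into behavioural-history classifications:

1. **Cohort simulation** — a synthetic 2x2 factorial cohort (sitting vs
   breaking up sitting x 9-h vs 5-h sleep opportunity; 22/22/20/20
   participants, ten 20-min drives each at 20 Hz, +-4 g) with the class-
   dependent movement signatures the networks must detect, plus cohort
   metadata (total sleep time, step counts) for ground-truth
   verification by Welch *t*-tests.
2. **Preparation** — CSV ingestion, scaling to g units, drive isolation
   via a manifest, task-specific exclusions, fixed-length windowing
   (4096 samples ≈ 200 s), and 5-fold 80/20 cross-validation splits at
   window or participant granularity.
3. **Training** — two 1D CNNs built on the package's own NumPy
   neural-network engine: **DixonNet** (four 100-filter kernel-16
   convolutions, one max-pool, GAP, dropout, linear head; 485,301
   parameters) and a **1D ResNet-18** (stride-2 stem, four residual
   stages of 64/128/256/512 filters, GAP, linear head). Binary
   cross-entropy, Adam, batch 64, reduce-on-plateau learning rate
   (÷10 after 10 non-improving epochs from 1e-4).
4. **CAM** — with last-conv activations `S_k(x)`, pooled features
   `f_k = mean_x S_k(x)` and head weights `w_k`, the class score is
   `g_c = Σ_k w_k^c f_k` and the activation map is
   `M_c(x) = Σ_k w_k^c S_k(x)`, upsampled to window length and rendered
   over the x/y/z traces (each panel on a constant 1-g scale) for the
   five highest- and five lowest-|logit| correctly classified windows
   per class.

See `docs/methods.md` for the full model description, parameter tables
and design rationale.

## Worked example

Run a scaled-down end-to-end experiment (8 participants, 2 experimental
days, 2-min drives, 512-sample windows, strong class separation) from the
bundled configuration:

```sh
acticam run --config examples/smoke.yaml
```

which simulates the cohort, trains DixonNet on both tasks with 2-fold
cross-validation, renders CAM exemplars, and prints:

```
sitting_history / dixonnet: accuracy 100.00 +- 0.00 %, F-score 1.000 +- 0.000
sleep_history / dixonnet: accuracy 74.22 +- 2.21 %, F-score 0.675 +- 0.022
```

Sitting history separates perfectly at this effect size because the two
activity classes differ in resting thigh pitch — a constant shift in how
gravity distributes over the axes that the network reads directly. Sleep
history is harder: the 5-h class shows quiet spells punctuated by large
abrupt movements while the 9-h class moves frequently at ordinary
amplitude, a nonlinear signature that needs more training than this
two-minute demo provides (the acceptance-scale run below reaches >= 90%).
`scratch/smoke-run/` then contains the cohort metadata and manifest,
`ground_truth.json` (here: sleep *t* = 10.1, p = 6.7e-05; steps
*t* = -15.0, p = 1.5e-04 — both manipulation checks reject), and per
task/architecture `metrics.json`, confusion matrices, epoch logs,
learning-curve plots, fold checkpoints and `cam_*.png` exemplar maps.

The individual stages are also available as `acticam simulate`,
`acticam prepare`, `acticam train` and `acticam cam`, operating on the
documented CSV dialects, so real ActivPAL-style exports can be dropped in
place of the simulator's output.

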