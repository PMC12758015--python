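# qusmigrate

Cross-scanner migration of quantitative-ultrasound (QUS) deep classifiers in
a black-box setting — with a built-in RF speckle simulator so the entire
pipeline runs end to end without any real data.

## The problem

A tissue classifier trained on RF data from one ultrasound scanner (the
*victim* machine) does not transfer to another scanner (the *perpetrator*
machine): the received spectrum factors as `I(f, x) = S(f, x)·P(f, x)`, and
the machine-specific system response `S` differs in pulse band, gain, and
sampling rate. If only an input–output score interface of the victim model is
available, together with unlabeled data from the perpetrator machine, its
functionality can nevertheless be migrated:

1. **Calibrate.** Image one calibration phantom with both machines; the
   tissue term cancels in the depth-gated spectral ratio, leaving the
   transfer function `Γ(f, x) = S_victim/S_perpetrator`, applied in its
   Wiener-regularized form `Γ_W = |Γ|⁻¹ / (|Γ|⁻² + SNR⁻¹)`.
2. **Pseudo-label.** Map unlabeled perpetrator patches into the victim's
   domain (`Γ_W·X_perp`), query the opaque victim interface, and threshold
   the scores at the label-distribution prior (the median for a balanced
   task).
3. **Refine.** Iterative learning with noisy labels: per denoising cycle,
   re-initialize the perpetrator model and train it on *anchors* — the
   (1 − ε) fraction of points with the lowest current cross-entropy,
   re-selected every epoch (noise-rate prior ε = 0.2) — then re-acquire
   pseudo-labels from the refined model.
4. **Deploy.** Train a final model on the raw perpetrator patches with the
   refined labels: a classifier native to the perpetrator machine.

The package is relevant both as a model-security demonstration (functionality
theft across scanners) and as a regulatory tool (building open reference
models from proprietary ones through their interfaces).

## Worked example

```python
import numpy as np
from qusmigrate.experiments import make_benchmark, migrate_once

bench = make_benchmark(seed=1)          # simulate machines, train victim, fit Gamma
print(bench.victim_val_metrics)
r = migrate_once(bench, seed=101)       # black-box migration, one replicate
print({k: round(v, 2) for k, v in r.items() if isinstance(v, float)})
```

prints (desk-scale geometry, reduced CNNs, one CPU):

```
{'accuracy_pct': 100.0, 'auc': 1.0, 'n': 320}
{'percentile': 50.0, 'epsilon': 0.2, 'initial_pseudo_label_accuracy_pct': 67.71,
 'final_label_accuracy_pct': 100.0, 'accuracy_pct': 100.0, 'auc': 1.0}
```

Reading: the victim model scores 100% on its own validation data; raw victim
scores on calibrated perpetrator patches give 68% correct pseudo-labels,
which two denoising cycles refine to 100%; the final perpetrator-native
model classifies the held-out perpetrator test patches at 100% / AUC 1.0.
Without the transfer function the victim systematically mislabels the raw
5 MHz-band patches and the same pipeline collapses — the calibration step is
what makes the black-box migration work.

The same stages are scriptable from the shell:

```bash
qusmigrate simulate --calibration --out cal.h5 --n-frames 10 --seed 0
qusmigrate calibrate --victim cal.victim.h5 --perp cal.perp.h5 --out tf.h5
qusmigrate simulate --machine perpetrator --out perp.h5 --n-frames 10 --seed 1
qusmigrate patchify --in perp.h5 --out patches.h5
qusmigrate migrate --seed 1 --seeds 5 --out run/
```

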