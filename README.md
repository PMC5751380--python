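# gaitjsrc

Compressed-domain classification of multi-sensor gait and activity signals.

## The problem

Wearable body-sensor networks for gait telemonitoring face two coupled
constraints: each sensor node must transmit as little as possible (radio
dominates its energy budget), and the receiver must still classify the
activity accurately.  `gaitjsrc` implements a pipeline that addresses both
at once:

* **Distributed compressed sensing (DCS).**  The J sensor signals are
  modeled as *jointly sparse with a shared support* (the JSM-2 model):
  x_j = Ψθ_j with one support set Ω common to all sensors.  Each node
  compresses its own windowed signal independently with a random block
  Φ_j — sparse-binary (two unit entries per column) or Gaussian — so the
  ensemble operator is block-diagonal and the compression ratio is
  CR = (N − M)/N × 100%.
* **Joint sparse representation classification (JSRC).**  Test windows are
  labeled *directly in the compressed domain* — no reconstruction.  The
  dictionary's atoms are the compressed training windows; a test vector is
  coded with one task per sensor under a shared row support (an l2/l0
  mixed-norm program, solved by simultaneous orthogonal matching pursuit
  or by a multitask Bayesian solver), and labeled by the minimal
  class-masked residual ‖Y − A δ_i(W)‖₂.
* **Neighbor pruning (SRCC).**  Before coding, the dictionary is pruned
  per test sample: per-sensor ridge coefficients over all atoms are
  computed in closed form, their magnitudes averaged across sensors, and
  only the m top-scoring atoms of each class are kept — cutting the
  per-sample cost from O(w²n) to O(w²Lm).  KNN pruning and SRC/KNN/naive
  Bayes baselines are included for comparison.

The package is aimed at researchers in wearable-sensor activity
recognition and compressive sensing who need a reproducible, testable
reference implementation: every stage (synthetic ground-truth generators,
filtering/windowing, measurement, solvers, metrics, subject-wise
cross-validation) is a plain library function, with a thin CLI on top.

## Worked example

```python
import gaitjsrc as g

# A synthetic cohort: 8 subjects x 4 activity classes x 6 windows,
# 5 sensors, 200-sample windows at 20 Hz.
ds = g.simulate_gait_dataset(8, 4, 6, J=5, window_len=200, seed=0)

# Subject-wise 4-fold CV of the SRCC-pruned compressed-domain classifier
# at 70% compression with 10 neighbors per class.
res = g.run_cv(ds, g.ModelSettings(cr=70.0, m=10, k=20), outer_folds=4)
print("samples:", ds.n)
print(f"pooled accuracy: {res.accuracy:.2f}%")
```

prints

```
samples: 192
pooled accuracy: 100.00%
```

Every window was compressed from 200 to 60 samples per channel on its
(virtual) sensor, and classification used only those measurements: the
pooled accuracy is the fraction of held-out-subject windows labeled
correctly.  On this cohort the classes are cleanly separable, so accuracy
sits at the ceiling; raising the compression ratio toward 95% or the noise
level degrades it.

The same experiment from the shell:

```bash
gaitjsrc simulate --subjects 8 --classes 4 --windows 6 --out ds.npz
gaitjsrc evaluate --dataset ds.npz --cr 70 --m 10 --folds 4 --out summary.json
gaitjsrc sweep --dataset ds.npz --cr-grid 10,30,50,70,90 --m-grid 10,20 --out sweep.csv
```

A worked confusion-table example ships in `gaitjsrc.examples`: a reference
nine-activity, 20-subject experiment (200 test windows per class).
Feeding its counts through `confusion_metrics` gives an overall accuracy
of 95.1% and, e.g., a "standing" recall of 93% (186 of 200 windows).

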