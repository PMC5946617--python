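# memcolour

Bayesian cue-fusion modelling of the **memory colour effect** in
achromatic-adjustment psychophysics.

Colour-diagnostic objects — a banana, a lemon, a mailbox — look slightly
tinted in their typical colour even when they are colourimetrically
grey.  When observers adjust such an object until it *appears* grey,
they compensate by overshooting opposite the typical hue; the size of
that compensating shift is the measured memory colour effect.
`memcolour` is for researchers in colour perception and Bayesian
modelling who want to model, evaluate, and simulate this effect from
repeated colour adjustments in the isoluminant chromaticity plane of the
Derrington–Krauskopf–Lennie (DKL) colour space, with background grey at
the origin.

## The model

All adjustments for a stimulus are projected onto its *typical-hue
axis* (the unit direction of the mean typical adjustment).  Two Gaussian
cues are estimated from the projections:

* the **prior** *P* — mean and variance of repeated *typical*
  adjustments (the remembered typical colour and its precision), and
* the **signal** *S* — mean and variance of repeated *grey* adjustments
  of a colour-neutral disk (the noise of grey perception).

With reliabilities *r* = 1/var, the predicted memory colour effect is
the precision-weighted average

```
M  = w1 · P + w2 · S        w1 = r1 / (r1 + r2),   w2 = 1 − w1
SD = sqrt(1 / (r1 + r2))
```

The model has **no free parameters**: everything is determined by the
adjustment data.  Because *S* sits at grey and *P* toward the typical
colour, 0 ≤ M ≤ P — the model cannot predict null or negative effects,
which is itself a testable structural property.

Predicted effects are compared with measured ones three ways: per
observer (Fisher-z correlations t-tested across observers), pooled over
all observer × stimulus pairs, and aggregated across stimuli, where the
cue variances are variances of per-observer means (the var/n,
standard-error construction).  Condition-centred *relative* effects and
a paired predicted-vs-measured difference test round out the toolkit,
and a virtual-observer generator produces experiment-shaped synthetic
datasets with closed-form ground truth for validation and power work.

## Worked example

One observer adjusted a banana image to its remembered yellow five
times, and a neutral disk to grey five times (projections onto the
banana's hue axis, DKL-plane units):

```python
from memcolour import predict_effect

typical   = [0.28, 0.31, 0.26, 0.33, 0.30]
disk_grey = [0.04, -0.06, 0.01, 0.07, -0.03]
post = predict_effect(typical, disk_grey)
```

prints (see `examples/fuse_cues.py`):

```
prior weight w1      = 0.789
predicted effect M   = 0.2348
posterior SD         = 0.0240
```

The colour memory is more reliable than grey perception here, so the
prior carries weight 0.79 and the model expects grey adjustments of the
banana to shift 0.23 plane units opposite its typical hue.  A full
simulated study:

```bash
python examples/simulate_and_evaluate.py
```

```
  approach condition  effects   n        r  df         t            p
individual       all absolute  15 0.866223  14 11.646784 6.856012e-09
    pooled       all absolute 105 0.768740 103 12.198752 5.137336e-22
aggregated       all absolute   7 0.975542   5  9.923698 8.867073e-05

condition  n     delta         t  df        p
      all  7 -0.010147 -0.821842   6 0.442593
```

On model-conforming synthetic data all three approaches recover the
model (r ≈ 0.87–0.98) and the difference test finds no systematic
over- or under-prediction (delta ≈ −0.01, p = 0.44).  The other example
scripts show noise attenuation of individual-level predictions
(`noise_attenuation.py`) and model-violating stimuli with exclusion
reanalysis (`model_violations.py`).

The same pipeline is scriptable from the shell:

```bash
memcolour simulate --seed 7 --out run/
memcolour evaluate --data run/adjustments.csv --out run/results/
```

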