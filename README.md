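# dyadsync

Quantification and prediction of nonverbal behavior in dyadic interactions.

When two people interact, their body movements and facial expressions become
temporally linked — *interactional synchrony*. `dyadsync` implements a full
analysis pipeline for motion-capture recordings of interacting pairs:
skeletal joint positions (17 upper-body joints at a nominal 30 Hz), facial
blendshape channels (52 values in [0, 1]), head rotation and point of gaze,
together with questionnaire outcomes (an 8-item interpersonal-attraction
composite, 15-item self/observer personality profiles, emotion-word
percentages). Because raw recordings of this kind are not publicly
available, the package includes a first-class synthetic dyad generator with
analytically controlled coupling, which every stage is tested against.

## What it computes

**Synchrony.** Each participant's *extent of bodily movement* is the
per-frame Euclidean displacement of each joint, averaged across the 17
joints. Raw non-uniform frames are linearly interpolated to 30 Hz, passed
through a second-order zero-phase Butterworth low-pass at 6 Hz, and brought
to 10 Hz. The two partners' series x, y are then cross-correlated within
consecutive non-overlapping 100-s windows over a lag grid

    r_w(tau) = corr( x(t), y(t + tau) ),   tau = -L, ..., -0.1, 0, 0.1, ..., L

with L = 5 s for body and 1 s for facial movement (101 and 21 lags). A
window is discarded when less than 90% of either partner's frames are valid.
Five summaries are taken over the (window, lag) cells: mean, absolute mean,
mean of non-negative values, maximum, and the signed value of the largest
magnitude.

**Features and classification.** A deterministic enumeration of 878
candidate features per participant (synchrony summaries per joint, joint
angle and blendshape channel; descriptive statistics of coordinates,
angles, head rotation, gaze; validity measures; gender) feeds a
correlation-based feature-selection step (CFS merit search) followed by
linear SVM recursive feature elimination down to 23 features — both fitted
on training data only. Participants are labeled high/low attraction by a
median split of the questionnaire composite and classified with a
500-tree random forest and a one-hidden-layer (50-unit, logistic)
multilayer perceptron, evaluated by five-fold cross-validation and a
held-out 30% test set against the majority-class baseline. Splits group by
dyad by default, since synchrony features are shared within a pair.

## Worked example

```python
from dyadsync import run_pipeline, report_render
from dyadsync.config import PipelineConfig, SynthConfig

synth = SynthConfig(duration_s=120.0, coupling_alpha=0.6, coupling_lag_s=0.3,
                    attraction_effect_size=0.8)
report, table = run_pipeline(PipelineConfig(), synth, n_dyads=24, seed=7)
print(report_render(report))
```

prints (abbreviated):

```
- dyads: 24 (48 participants)
- body windows kept/dropped: 24/0
- cohort mean body synchrony (mean_r): 0.0118
- cohort mean face synchrony (mean_r): 0.1373

## Classifier: random_forest
- CV accuracy: 97.50% (SD = 5.00%)
- test accuracy: 81.25% (majority baseline 56.25%)
- confusion: {'tp': 4, 'tn': 9, 'fp': 0, 'fn': 3}
```

The mean synchrony scores average r over *all* lags and windows, so even a
strongly coupled dyad yields a small positive number for the body (the
correlation decays away from the true lag) and a larger one for the face
(shorter lag grid). Both classifiers recover the injected attraction
effect well above the 56.25% baseline; with `attraction_effect_size=0` they
fall back to baseline, which is the package's leakage check.

The same run is available from the shell:

```bash
dyadsync run --synthetic --n-dyads 24 --seed 7 --out out/
```

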