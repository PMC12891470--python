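# gaitstab

Trunk-accelerometry gait-stability analysis for people with stroke (PwS) vs
healthy controls (HC): a tested, reusable implementation of a two-step
machine-learning pipeline for wearable-sensor gait data, together with a
synthetic-cohort generator that makes every stage verifiable without
participant data.

## The problem

After a stroke, walking on uneven ground exposes people to unpredictable
perturbations that linear gait statistics capture poorly. A single lumbar
(L3) accelerometer yields a rich set of stability indicators per axis
(anteroposterior AP, mediolateral ML, vertical VT):

* **RMS** — root-mean-square of the demeaned acceleration normalized by
  squared gait speed (variability magnitude),
* **HR** — harmonic ratio, Σ even-harmonic / Σ odd-harmonic amplitudes of
  the stride-frequency spectrum (odd/even for ML): smoothness and step
  symmetry,
* **SampEn** — sample entropy, −ln A/B with template length m = 2 and
  tolerance r = 0.2·SD: irregularity,
* **RQA %REC / %DET** — recurrence rate and determinism of the delay-embedded
  trajectory: periodicity,
* **sLE** — short-term maximum Lyapunov exponent (Rosenstein
  nearest-neighbor divergence over the first half stride, per stride):
  local dynamic stability.

**Step 1** discriminates stroke-like from control-like subjects from these
features under class imbalance (71 vs 39), comparing augmentation
strategies (SMOTE, GAN, conditional GAN — training split only) across six
classifiers with repeated stratified 80/20 evaluation, plus sparse PLS-DA
with VIP scores. **Step 2** predicts uneven-surface stability metrics and
gait speed from even-surface parameters with six regressors and interprets
the fits with odds ratios, partial-dependence curves and Shapley
attributions.

Because cohorts like this are not freely shareable, the package ships a
first-class synthetic generator whose cohorts embed the structures the
analysis is meant to find: a Cohen's d ≈ 0.7 group shift on
RMS/SampEn/HR features, a 0.8 m/s gait-speed breakpoint, a U-shaped
dependence of SampEn_AP on ankle dorsiflexion at initial contact, and an
HR_AP plateau near 1.5. Every generative parameter is returned as ground
truth for recovery tests.

## Worked example

```python
from gaitstab.synthetic import CohortSpec, simulate_subject
from gaitstab.events import detect_gait_events, trim_transient_strides
from gaitstab.metrics import compute_all

spec = CohortSpec()
rec = simulate_subject(spec, "HC", seed=1)
events = trim_transient_strides(detect_gait_events(rec.shank_ap, spec.fs))
feats = compute_all(rec.trunk, events, rec.gait_speed)
print({k: round(v, 3) for k, v in feats.values.items() if k.endswith("_AP")})
```

prints (control-like subject, 10 analyzed cycles):

```
{'RMS_AP': 0.431, 'HR_AP': 2.552, 'SampEn_AP': 0.679,
 'RQA_rec_AP': 5.05, 'RQA_det_AP': 91.917, 'sLE_AP': 0.317}
```

RMS_AP is the speed-normalized acceleration variability; HR_AP ≈ 3 says the
AP spectrum is dominated by even stride harmonics (smooth, symmetric steps);
SampEn, %REC/%DET and sLE quantify irregularity, periodicity and local
divergence of the same window. A stroke-like subject from the same generator
shows higher RMS/SampEn and an HR_AP nearer 1.

The full pipeline is also scriptable from the shell:

```bash
gaitstab --show-config                 # all defaults
gaitstab simulate --out cohort
gaitstab classify --features cohort/classification_features.csv --out step1
gaitstab regress  --table cohort/regression_table.csv --out step2
gaitstab interpret --table cohort/regression_table.csv --out interp
gaitstab report --indir . --out summary
```

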