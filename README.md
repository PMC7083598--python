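# salieeg

EEG analysis of the push–pull competition between top-down and bottom-up
auditory attention, packaged as a reusable, fully tested pipeline driven
by a seeded synthetic-data generator.

## The scientific problem

Listeners attending a rhythmic tone stream (440 Hz tones at 2.6 Hz) while
ignoring a busy natural soundscape show two opposing modulations of the
same neural markers: attended targets *enhance*, and salient background
events *suppress*,

- phase-locking to the tone rhythm — quantified as the spectral energy at
  2.6 Hz of concatenated six-tone (2.3 s) segments, normalized by the
  mean energy at 2.55–2.65 Hz, compared post- versus pre-onset;
- high-gamma (70–110 Hz) power — band power in the window +1.5…+3.5 s
  post-onset minus −2.5…−0.5 s, in dB,

with the suppression graded by the behavioral salience tier (high / mid /
low tertiles of event strength, `0.5·z(slope) + 0.5·z(peak)` of the
salience curve). Around high-salience events, reconstruction of the
*ignored* scene envelope from EEG — a backward ridge model
`W = (XᵀX + λI)⁻¹XᵀY` with 0–250 ms lags, λ = 2²⁰, trained
leave-one-scene-out and scored by 1 s sliding-window correlation —
transiently improves. Source-level gamma maps (sLORETA on a leadfield,
unique-voxel masking against control tones) feed a cross-lag sparse
non-negative CCA whose permutation-calibrated significance grid shows the
bottom-up and top-down attention networks overlapping, with bottom-up
engagement leading by ~0.5 s. Finally, a small feed-forward classifier
predicts whether a tone lies just before or just after a salient event
from the tone-locking and gamma features, and interaction information
I(F1,F2;S) − I(F1;S) − I(F2;S) quantifies their synergy.

The original 12-subject recordings are not public, so the package ships a
generator (`salieeg.simulate`) that emulates the stimuli, salience
structure, and all injected neural effects with known ground truth;
every analysis stage is validated by recovering those injections. See
`docs/methods.md` for the model, parameters, and design choices.

## Worked example

```python
from salieeg import desk_config, RunConfig, run_pipeline

cfg = RunConfig(sim=desk_config(seed=1), n_controls_per_scene=8)
report = run_pipeline(cfg, out_dir="run1")

tl = report["tonelock"]
print(f"tone-locking change, targets: {tl['target']['mean_change']:+.2f} "
      f"(t={tl['target']['t']:.2f}, p={tl['target']['p']:.1e})")
print(f"tone-locking change, events:  {tl['salient']['mean_change']:+.2f} "
      f"(t={tl['salient']['t']:.2f}, p={tl['salient']['p']:.1e})")
gm = report["gamma"]["tiers"]
print("gamma change by tier (dB):",
      {t: round(gm[t]['mean_change_db'], 2) for t in ('high', 'mid', 'low')})
print("network lead (s):", round(report["scca"]["peak_offset_s"], 3))
print("prediction AUC:", {k: round(v, 3)
                          for k, v in report["classify"]["auc"].items()})
```

Output for seed 1:

```
tone-locking change, targets: +0.22 (t=1.28, p=2.3e-01)
tone-locking change, events:  -0.66 (t=-4.82, p=5.3e-04)
gamma change by tier (dB): {'high': -4.19, 'mid': -2.98, 'low': -1.18}
network lead (s): 0.52
prediction AUC: {'gamma': 0.851, 'locking': 0.522, 'both': 0.842}
```

Event-related suppression of phase-locking is clearly detected; target
enhancement is positive but underpowered at this miniature scale (the
dedicated recovery studies in `tests/test_acceptance.py` use longer
sessions, where the +30% injection is detected reliably — see the
methods note on the statistic's resolution requirements). Gamma
suppression is graded by tier (injected −3/−1.5/0 dB; the dense session
adds burst-spillover bias, also discussed in the methods note), the
bottom-up network leads top-down by ~0.5 s (true lead 0.5 s), and the
classifier separates before- from after-event tones well above chance.
A command-line interface mirrors the stages
(`salieeg simulate|preprocess|events|tonelock|gamma|decode|scca|classify|stats|run-all|report`).

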