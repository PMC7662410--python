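# ansrecall

Modeling autonomic nervous system (ANS) response and advertisement recall
from physiological signals. The package provides a complete, testable
pipeline:

- **`ansrecall.simulate`** — synthetic ground truth: NN-interval series with
  controllable LF/HF spectral content, ECG traces with beats at prescribed
  times, EDA traces with tonic drift plus discrete skin-conductance
  responses, and indicator tables drawn from a latent path model with known
  loadings and path coefficients.
- **`ansrecall.hrv`** — R-peak detection (band-pass/derivative/energy
  detector with a 200 ms refractory period), NN-interval construction with
  ectopic-beat exclusion, and time-/frequency-domain HRV indices (AVNN,
  SDNN, RMSSD, pNN50, normalized LF/HF power, LF/HF ratio).
- **`ansrecall.eda`** — electrodermal decomposition: tonic skin-conductance
  level via a zero-phase 0.1 Hz low-pass, and SCR counting via the
  downsample-to-20 Hz / differentiate / 20-point-Bartlett pipeline.
- **`ansrecall.recall`** — questionnaire scoring to a 0–15 recall score
  with a configurable item scheme (shipped default: equal weights).
- **`ansrecall.plspm`** — from-scratch partial least squares path modeling:
  reflective (Mode A) outer estimation with path/centroid/factorial inner
  schemes, sign alignment of indicator blocks, OLS structural coefficients,
  communalities, R², goodness of fit, bootstrap confidence intervals, and a
  permutation test for two-group path differences.
- **`ansrecall.pipeline`** / **`ansrecall.cli`** — single-config
  orchestration: segment recordings on a stimulus schedule (1 min baseline
  + six 1 min spots by default), extract features, assemble the per-spot
  indicator tables (`lf, sdnn, ns_scr, mean_scl, hf, pnn50, rmssd, lf_hf,
  avnn, recall_score, gender`), fit one path model per spot
  (Sympathetic→ANS, Vagal→ANS, ANS→Recall), and report.

## CLI

```sh
# end-to-end study from a config (synthetic signals or table mode)
ansrecall run --config examples/study.yaml --out out/

# or stage by stage
ansrecall simulate --config examples/study.yaml --out study/
ansrecall features --recordings study/recordings \
    --recall-scores study/recall_scores.csv --genders study/genders.csv \
    --out study/table.csv
ansrecall fit --table study/table.csv --out study/fits.json
ansrecall report --report out/report.json --out out/tables
```

A config looks like:

```yaml
seed: 11
synthetic:
  mode: signals        # or "table" for direct indicator-table generation
  n_subjects: 20
  fs_hz: 250
schedule: default      # 60 s baseline + six 60 s spots
model: default         # Sympathetic/Vagal -> ANS -> Recall
analysis:
  n_boot: 500
  n_perm: 199
  alpha: 0.05
```

Reports are deterministic given the seed: rerunning the same config
produces a byte-identical `report.json`.

## Notes and caveats

- One-minute epochs give ~0.017 Hz spectral resolution; VLF power on such
  epochs is poorly resolved, and the normalized LF/HF powers follow the
  total-minus-VLF convention regardless.
- pNN50 is reported as a proportion in [0, 1] of successive-difference
  pairs exceeding 50 ms.
- The SCR threshold and the 1 s minimum inter-event separation are
  documented defaults (scale-adaptive: `max(0.01, 3×MAD)` on the spiky
  signal); no numeric threshold is prescribed by the underlying detection
  scheme.
- No multiple-testing correction is applied across spots or edges; the
  report says so in its provenance block.
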