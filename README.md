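# retrogate

Intrinsic retrospective cardiac gating for micro-CT, with cardiac-function
quantification, validated end to end on a synthetic 4D beating
mouse-thorax phantom.

## The problem

Imaging a beating mouse heart with micro-CT is hard: at 300–700 beats per
minute a full cardiac cycle lasts 85–200 ms, far shorter than a CT
rotation, and breathing adds a second, slower motion. Hardware gating
(ECG electrodes, breathing cushions) complicates animal handling.
*Retrospective intrinsic* gating instead recovers both physiological
signals **from the projection data itself** after the scan: every
projection is time-stamped, the respiratory and cardiac signals are read
out of the projections, inspiration-blurred frames are discarded, and the
remaining projections are sorted by cardiac phase and reconstructed
phase by phase into a 4D (3D + cardiac phase) image, from which ejection
fraction and myocardial strain follow.

This package implements that pipeline for researchers who want to study,
extend or benchmark projection-domain gating without scanner access:
every stage runs against a digital thorax phantom whose cardiac and
respiratory state is analytically known, so each output can be checked
against exact ground truth.

## The method

Given projections p_i acquired continuously at frame rate f_s:

1. **ROI placement** — a thorax template is co-registered onto the
   projections by maximizing mutual information over integer
   translations; the template carries a cardiac ROI (heart / upper
   thoracic cavity) and a respiratory ROI (lower thoracic cavity /
   diaphragm).
2. **Signal extraction** — s[i] = Σ_{d∈ROI} p_i[d]: per-projection ROI
   intensity sums give the raw cardiac and respiratory time series.
3. **Filtering & rate estimation** — zero-phase Butterworth band-passes
   (0.5–4 Hz respiratory, 5–12 Hz cardiac, i.e. 30–240 breaths/min and
   300–720 bpm) and a Hann-windowed, zero-padded spectral peak give the
   respiratory rate and heart rate; rates up to at least 600 bpm are
   detectable at the default 40 Hz frame rate.
4. **Inspiration rejection** — samples in the upper amplitude quantile
   (default 0.70) of the filtered respiratory signal within a sliding
   3-cycle window are discarded; with the default 30% inspiratory duty
   cycle ~70% of projections are retained.
5. **Phase assignment & binning** — beats are detected as peaks of the
   (rate-adaptively re-filtered) cardiac signal; each projection gets its
   cardiac-cycle fraction (t − t_prev)/(t_next − t_prev), which is exact
   under beat-to-beat cycle-length variation, and is grouped into 12
   equal phases (phase 1: 0–8.33% of the cycle, phase 2: 8.33–16.67%, …).
   At 400 bpm the cycle is 150 ms and each phase 12.5 ms.
6. **Reconstruction** — each phase bin is reconstructed by parallel-beam
   FBP (Ram-Lak/Shepp-Logan) or, preferably, ordered-subset SIRT, whose
   image levels are consistent across phases regardless of how many
   projections each bin received.
7. **Cardiac function** — the contrast-filled LV cavity is segmented per
   phase (Otsu within a cardiac window); EDV/ESV are the max/min cavity
   volumes, EF = (EDV−ESV)/EDV·100, FS = (LVIDd−LVIDs)/LVIDd·100, and
   segmental strain ΔL/L₀ is measured along the endocardial contour in 6
   segments (posterior base → anterior base); EF stratifies heart-failure
   severity (severe <20%, moderate 20–40%, mild >40%).

## Worked example

```python
from retrogate import RunConfig, run

report = run(RunConfig(seed=1, out_dir="run1"))
print(report["est_cardiac_bpm"], report["retained_fraction"])
print(report["metrics"]["ef_pct"], report["metrics"]["hf_class"])
```

This simulates a 60 s scan (2400 projections at 40 fps) of the default
phantom — a 400 bpm heart with 5% beat-length jitter and an 80 /min
respiratory cycle — gates it, reconstructs 12 phases with ordered-subset
SIRT and measures cardiac function. Output printed by this exact run:

```
403.0356360369168 0.70125
58.02650957290132 mild
```

i.e. the heart rate is recovered to 0.8% (403.0 vs a realized jittered
mean near 400 bpm), 70.1% of projections survive inspiration rejection,
and the measured EF of 58.0% is within 2.1 points of the phantom's
ground-truth area-EF of 60.1% (contraction factor 0.632), classified as
a healthy ("mild") heart. The same pipeline is scriptable from a shell:

```bash
retrogate run --seed 1 --out run1
retrogate simulate --out stream --seed 1 --duration 60
retrogate make-template --out tpl.npz
retrogate gate --stream stream --template tpl.npz --out gating.csv
retrogate recon --stream stream --gating gating.csv --method ositer --out phases
retrogate metrics --phases phases --pixel-mm 0.2 --est-bpm 403 --out metrics.json
```

## Layout

- `src/retrogate/phantom.py` — 4D digital thorax with analytic truth
- `src/retrogate/acquisition.py` — parallel-beam projector (+ exact
  adjoint), continuous-rotation scan simulation, Poisson noise, stream I/O
- `src/retrogate/gating.py` — the gating algorithm
- `src/retrogate/recon.py` — FBP and ordered-subset SIRT
- `src/retrogate/cardiofunc.py` — EF / FS / strain / severity classes
- `src/retrogate/pipeline.py`, `cli.py` — orchestration, config, CLI

See `docs/methods.md` for the model details, parameter choices and known
limitations.
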