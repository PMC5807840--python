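# cica-rppg

Remote photoplethysmography (rPPG) estimates the cardiac blood-volume
pulse from ordinary video of skin: the arterial pulse causes minute
periodic color changes that survive spatial averaging of skin pixels.
This package extracts that pulse from 3×N RGB temporal traces by
**constrained one-unit independent component analysis**: it searches for
the demixing weight vector w whose projection y = wᵀx is maximally
non-Gaussian, while two inequality constraints anchor the search to
physiology —

* **periodicity**: the mean squared autocorrelation of y (lag 0
  excluded), E{r²} = (1/N) Σₖ (wᵀMₖw)² with Mₖ = x Tₖ xᵀ, must exceed a
  threshold ζ₁;
* **chrominance**: w must stay within distance ζ₂ (on the unit sphere,
  sign-aligned) of the CHROM skin-tone weights
  w_chrom = (3(1−α/2), −2(1+α/2), 3α/2), α = σ(Xf)/σ(Yf), where
  Xf = 3R_f − 2G_f and Yf = 1.5R_f + G_f − 1.5B_f are band-passed
  skin-tone projections.

The objective is the FastICA negentropy approximation
J(y) = ρ[E{G(y)} − E{G(v)}]² with G(u) = log cosh(au)/a, maximized
subject to g₁ ≤ 0, g₂ ≤ 0 and the unit-variance equality E{y²} = 1
(which whitening reduces to ‖w‖ = 1).  The problem is solved per sliding
window (30 s, 0.5 s stride) with analytic gradients, warm-started from
the previous window; the heart rate is the highest FFT peak of y in the
physiological band 0.7–3 Hz, and the HR series is smoothed by a scalar
random-walk Kalman filter.  CHROM and GREEN baseline extractors, a
ground-truth-bearing synthetic scene simulator, and the standard rPPG
metrics (MAE, spectral SNR, Pearson r, PRECIS 2.5/5) are included.

It is aimed at researchers working on camera-based vital-sign
measurement who need a reproducible, fully scriptable cICA reference
implementation with synthetic ground truth.

## Worked example

```bash
# simulate a 60 s scene at 72 bpm with known ground truth
cica-rppg simulate --preset clean --duration 60 --hr 72 --seed 7 \
    --out-traces traces.csv --out-truth truth.csv
# run the constrained-ICA pipeline
python - <<'PY'
import numpy as np
from cica_rppg import read_traces_csv
from cica_rppg.hr_pipeline import PipelineConfig, sliding_window_extract

traces = read_traces_csv("traces.csv")
hrs = sliding_window_extract(traces, PipelineConfig())
print(f"windows: {len(hrs.t)}")
print(f"median HR: {np.nanmedian(hrs.hr_raw):.1f} bpm")
print(f"HR MAE vs 72 bpm: {np.nanmean(abs(hrs.hr_raw - 72)):.2f} bpm")
PY
```

Output:

```
windows: 61
median HR: 72.1 bpm
HR MAE vs 72 bpm: 0.08 bpm
```

61 windows is a 60 s recording at a 30 s window and 0.5 s stride; the
median window HR of 72.1 bpm matches the simulated rate to within the
≈0.25 bpm spectral resolution of the padded FFT, and the 0.08 bpm mean
absolute error says every window locked onto the true pulse.  The same
pipeline runs from a YAML config with `cica-rppg run --config cfg.yaml`,
writing `pulse.csv`, `hr.csv`, `metrics.json` (when ground truth is
given) and a run log.

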