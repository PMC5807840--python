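"""Ground-truth-bearing simulator of rPPG scenes.

A scene is a linear mixture in the spirit of the ICA source model
x = A c + noise: a quasi-periodic cardiac pulse with a controllable
heart-rate trajectory is mixed into the three color channels along a
known unit direction, on top of a baseline skin color, an equal-on-all-
channels low-frequency drift, white sensor noise, and optionally a
strong periodic "motion" distractor at a distinct frequency with its own
color direction (emulating rhythmic motion in fitness recordings).

The generator stores every component it adds, so tests can assert the
exact reconstruction identity and score extraction quality against the
clean pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.signal import butter, filtfilt

from cica_rppg.ingest import TraceMatrix

#: Skin-plausible pulse color direction (G-dominant, all positive),
#: normalized.  The premise of chrominance methods is that the blood
#: volume pulse occupies a consistent direction of this kind.
DEFAULT_PULSE_DIRECTION = np.array([0.33, 0.61, 0.42]) / np.linalg.norm(
    [0.33, 0.61, 0.42]
)

#: Color direction of the periodic motion distractor: a bluish-tilted
#: shading/reflection direction (indoor ambient reflections are rarely
#: achromatic), distinct from the pulse direction.  Its two skin-tone
#: projections carry opposite signs, so the chrominance combination
#: cannot cancel it by tuning α; its coupling into the chrominance
#: signal is roughly half the pulse's, so the distractor confounds
#: chrominance extraction at 3× the pulse amplitude but not at 1× —
#: the regime the motion presets are built to span.
DEFAULT_MOTION_DIRECTION = np.array([0.45, 0.35, 0.82]) / np.linalg.norm(
    [0.45, 0.35, 0.82]
)


@dataclass
class MotionSpec:
    """Periodic motion distractor: frequency (Hz), amplitude, direction."""

    freq_hz: float = 1.6
    amp: float = 1.0
    direction: np.ndarray = field(
        default_factory=lambda: DEFAULT_MOTION_DIRECTION.copy()
    )

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)


@dataclass
class SyntheticScenario:
    """Full specification of a synthetic rPPG scene.

    ``hr_traj`` is either a constant in bpm or a callable t ↦ bpm.
    ``pulse_snr_db``, when given, overrides ``noise_sigma`` so that the
    total pulse variance across channels exceeds the total white-noise
    variance (3σ²) by the stated decibel ratio.
    """

    duration_s: float = 60.0
    fs: float = 30.0
    hr_traj: float | Callable[[np.ndarray], np.ndarray] = 72.0
    pulse_direction: np.ndarray = field(
        default_factory=lambda: DEFAULT_PULSE_DIRECTION.copy()
    )
    pulse_amp: float = 0.5
    harmonic_ratio: float = 0.3
    drift_amp: float = 2.0
    drift_cutoff_hz: float = 0.2
    noise_sigma: float = 0.05
    pulse_snr_db: Optional[float] = None
    motion: Optional[MotionSpec] = None
    baseline_rgb: np.ndarray = field(
        default_factory=lambda: np.array([140.0, 110.0, 95.0])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.pulse_direction = np.asarray(self.pulse_direction, dtype=float)
        self.pulse_direction = self.pulse_direction / np.linalg.norm(
            self.pulse_direction
        )
        self.baseline_rgb = np.asarray(self.baseline_rgb, dtype=float)
        if self.fs <= 6.0:
            raise ValueError("fs must exceed twice the 3 Hz physiological band")


@dataclass
class GroundTruth:
    """Everything the generator mixed in, for exact reconstruction."""

    pulse: np.ndarray          # clean unit-amplitude waveform
    hr: np.ndarray             # bpm per sample
    mixing: np.ndarray         # 3×K mixing matrix actually used
    components: np.ndarray     # K×N component signals (rows match mixing cols)
    drift: np.ndarray          # 3×N drift realization
    noise: np.ndarray          # 3×N white-noise realization
    baseline_rgb: np.ndarray


def generate_pulse(
    hr_traj: float | Callable[[np.ndarray], np.ndarray],
    fs: float,
    duration_s: float,
    harmonic_ratio: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic cardiac surrogate with a prescribed HR trajectory.

    The waveform is phase-integrated — φ(t) = 2π ∫ HR(t)/60 dt — so the
    instantaneous frequency tracks the trajectory exactly:
    pulse = sin φ + harmonic_ratio · sin 2φ.  Returns (pulse, hr_per_sample).
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    hr = np.full(n, float(hr_traj)) if np.isscalar(hr_traj) else np.asarray(
        hr_traj(t), dtype=float
    )
    if np.any(hr < 42.0) or np.any(hr > 180.0):
        raise ValueError("hr trajectory must stay within [42, 180] bpm")
    inst_freq = hr / 60.0
    phase = 2.0 * math.pi * np.cumsum(inst_freq) / fs
    pulse = np.sin(phase) + harmonic_ratio * np.sin(2.0 * phase)
    return pulse, hr


def _drift(n: int, fs: float, amp: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered white noise, rescaled to RMS amplitude ``amp``."""
    if amp == 0.0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    nyq = fs / 2.0
    b, a = butter(2, min(cutoff_hz / nyq, 0.99), btype="lowpass")
    low = filtfilt(b, a, raw)
    rms = np.sqrt(np.mean(low**2))
    return amp * low / rms if rms > 0 else np.zeros(n)


def mix_to_rgb(scenario: SyntheticScenario) -> tuple[TraceMatrix, GroundTruth]:
    """Mix a scenario into 3×N RGB traces with full ground truth.

    traces = baseline + pulse_amp·(pulse ⊗ pulse_dir) [+ motion term]
             + drift (identical on all channels) + white noise.
    The drift being equal on all channels deliberately exercises the
    intensity cancellation of chrominance processing.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_s * scenario.fs))
    pulse, hr = generate_pulse(
        scenario.hr_traj,
        scenario.fs,
        scenario.duration_s,
        scenario.harmonic_ratio,
        scenario.seed,
    )

    sigma = scenario.noise_sigma
    if scenario.pulse_snr_db is not None:
        # total pulse variance across channels vs total noise variance 3σ²
        p_pulse = scenario.pulse_amp**2 * float(np.var(pulse))
        sigma = math.sqrt(p_pulse / (3.0 * 10.0 ** (scenario.pulse_snr_db / 10.0)))

    components = [scenario.pulse_amp * pulse]
    mixing_cols = [scenario.pulse_direction]
    if scenario.motion is not None:
        t = np.arange(n) / scenario.fs
        motion_sig = scenario.motion.amp * np.sin(
            2.0 * math.pi * scenario.motion.freq_hz * t
        )
        components.append(motion_sig)
        mixing_cols.append(scenario.motion.direction)

    mixing = np.column_stack(mixing_cols)          # 3×K
    comp = np.vstack(components)                    # K×N
    drift_sig = _drift(n, scenario.fs, scenario.drift_amp, scenario.drift_cutoff_hz, rng)
    drift = np.tile(drift_sig, (3, 1))
    noise = sigma * rng.standard_normal((3, n))

    values = scenario.baseline_rgb[:, None] + mixing @ comp + drift + noise
    traces = TraceMatrix(values=values, fs=scenario.fs)
    truth = GroundTruth(
        pulse=pulse,
        hr=hr,
        mixing=mixing,
        components=comp,
        drift=drift,
        noise=noise,
        baseline_rgb=scenario.baseline_rgb.copy(),
    )
    return traces, truth


# --------------------------------------------------------------------------
# Motion presets (fitness-scenario analogues)
# --------------------------------------------------------------------------

#: Motion amplitude as a multiple of the pulse amplitude per preset.
PRESET_MOTION_FACTOR = {"clean": 0.0, "light": 1.0, "medium": 3.0, "intensive": 10.0}


def scenario_preset(
    name: str,
    duration_s: float = 60.0,
    hr_bpm: float = 72.0,
    motion_freq_hz: float = 1.6,
    seed: int = 0,
    **overrides,
) -> SyntheticScenario:
    """Named scene presets.

    ``clean`` has no motion; ``light``/``medium``/``intensive`` add a
    periodic motion distractor at 1×, 3× and 10× the pulse amplitude —
    qualitative analogues of increasingly vigorous rhythmic exercise.
    """
    name = name.lower()
    if name not in PRESET_MOTION_FACTOR:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_MOTION_FACTOR)}"
        )
    pulse_amp = overrides.pop("pulse_amp", 0.5)
    factor = PRESET_MOTION_FACTOR[name]
    motion = None
    if factor > 0:
        motion = MotionSpec(freq_hz=motion_freq_hz, amp=factor * pulse_amp)
    return SyntheticScenario(
        duration_s=duration_s,
        hr_traj=hr_bpm,
        pulse_amp=pulse_amp,
        motion=motion,
        seed=seed,
        **overrides,
    )


# --------------------------------------------------------------------------
# Video rendering (ingest round-trip)
# --------------------------------------------------------------------------

def render_video(
    traces: TraceMatrix,
    out_path: str | Path,
    frame_shape: tuple[int, int] = (48, 64),
) -> Path:
    """Render traces as a lossless 8-bit multi-page TIFF of uniform frames.

    Each frame is spatially uniform at the trace color, rounded to 8 bits
    (so a round trip through spatial averaging recovers the traces within
    the ±0.5 quantization bound).  Out-of-range values are clipped with a
    warning.
    """
    import warnings

    import tifffile

    out_path = Path(out_path)
    vals = traces.values
    if vals.min() < 0 or vals.max() > 255:
        warnings.warn("trace values outside [0, 255] clipped for 8-bit rendering")
        vals = np.clip(vals, 0, 255)
    h, w = frame_shape
    frames = np.empty((traces.n, h, w, 3), dtype=np.uint8)
    quant = np.rint(vals).astype(np.uint8)
    for i in range(traces.n):
        frames[i] = quant[:, i][None, None, :]
    tifffile.imwrite(str(out_path), frames, photometric="rgb")
    return out_path
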