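"""CHROM skin-tone projections, weights, and baseline pulse extractors.

The CHROM method projects band-passed RGB traces onto a standardized
skin-tone chrominance space,

    Xf = 3 R_f − 2 G_f
    Yf = 1.5 R_f + G_f − 1.5 B_f,

and combines them as S = Xf − α Yf with α = σ(Xf)/σ(Yf), which cancels
intensity (equal-on-all-channels) variations.  Expanding S in the RGB
channels gives the CHROM weight vector

    w_chrom(α) = (3(1 − α/2), −2(1 + α/2), 3α/2),

which anchors the chrominance constraint of the constrained-ICA solver.
Because α is a ratio of standard deviations, the model must be built on
non-whitened traces; :func:`map_weights_to_whitened` then carries the
weights into the whitened space where the solver operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cica_rppg.ingest import TraceMatrix
from cica_rppg.preprocess import (
    PreprocessConfig,
    Whitening,
    bandpass,
    detrend_smoothness_priors,
)


@dataclass
class ChromModel:
    """Skin-tone projections and the derived CHROM weights for one window."""

    Xf: np.ndarray
    Yf: np.ndarray
    alpha: float
    S: np.ndarray
    w_chrom: np.ndarray


def chrom_projection(x_f: TraceMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardized skin-tone projections (Xf, Yf) of band-passed traces."""
    vals = x_f.values if isinstance(x_f, TraceMatrix) else np.asarray(x_f, dtype=float)
    r, g, b = vals[0], vals[1], vals[2]
    xf = 3.0 * r - 2.0 * g
    yf = 1.5 * r + g - 1.5 * b
    return xf, yf


def chrom_alpha(xf: np.ndarray, yf: np.ndarray) -> float:
    """Ratio of sample standard deviations α = σ(Xf)/σ(Yf)."""
    sy = float(np.std(yf, ddof=1))
    if sy == 0.0:
        raise ValueError(
            "degenerate traces: σ(Yf) = 0, CHROM alpha undefined"
        )
    return float(np.std(xf, ddof=1)) / sy


def chrom_weights_from_alpha(alpha: float) -> np.ndarray:
    """CHROM weight vector (3(1−α/2), −2(1+α/2), 3α/2)."""
    return np.array(
        [3.0 * (1.0 - alpha / 2.0), -2.0 * (1.0 + alpha / 2.0), 3.0 * alpha / 2.0]
    )


def chrom_weights(x_f: TraceMatrix | np.ndarray) -> np.ndarray:
    """CHROM weights of band-passed traces; w_chromᵀ x_f = Xf − α Yf."""
    xf, yf = chrom_projection(x_f)
    return chrom_weights_from_alpha(chrom_alpha(xf, yf))


def chrom_model(x_f: TraceMatrix | np.ndarray) -> ChromModel:
    """Full chrominance model of one window of band-passed traces."""
    xf, yf = chrom_projection(x_f)
    alpha = chrom_alpha(xf, yf)
    return ChromModel(
        Xf=xf,
        Yf=yf,
        alpha=alpha,
        S=xf - alpha * yf,
        w_chrom=chrom_weights_from_alpha(alpha),
    )


def chrom_pulse(x: TraceMatrix, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """CHROM baseline pulse: detrend → band-pass → S = Xf − α Yf."""
    cfg = cfg or PreprocessConfig()
    xd = detrend_smoothness_priors(x, cfg.detrend_lambda)
    xf = bandpass(xd, cfg.band, cfg.filter_order)
    return chrom_model(xf).S


def green_pulse(x: TraceMatrix, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """GREEN baseline pulse: the detrended, band-passed G channel."""
    cfg = cfg or PreprocessConfig()
    xd = detrend_smoothness_priors(x, cfg.detrend_lambda)
    xf = bandpass(xd, cfg.band, cfg.filter_order)
    return xf.values[1].copy()


def map_weights_to_whitened(w_raw: np.ndarray, whitening: Whitening) -> np.ndarray:
    """Carry raw-trace weights into whitened coordinates, unit-normalized.

    y = w_rawᵀ x = w_rawᵀ V_inv z, so the whitened-space weight is
    V_invᵀ w_raw (up to scale, which the unit-variance constraint fixes).
    """
    w = whitening.V_inv.T @ np.asarray(w_raw, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValueError("weight vector maps to zero in whitened space")
    return w / norm
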