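"""Detrending, centering, whitening and band-pass filtering of RGB traces.

Two preprocessing paths feed the extraction stage:

* the ICA path — detrend, center, whiten.  Whitening makes the channel
  covariance the identity, so the unit-variance constraint on the output
  reduces to a unit-norm constraint on the weight vector.
* the chrominance path — detrend and band-pass only.  The CHROM weights
  are built from the ratio of standard deviations of two skin-tone
  projections, which whitening would destroy, so the chrominance model is
  always computed on non-whitened traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import butter, filtfilt

from cica_rppg.ingest import TraceMatrix


@dataclass
class PreprocessConfig:
    """Parameters of the trace-conditioning stage.

    detrend_lambda
        Regularizer of the smoothness-priors detrender.  Larger values
        remove only slower trends: the operator's gain at frequency f is
        1 − 1/(1 + 16 λ² sin⁴(π f / fs)), so λ=300 at 30 Hz puts the
        half-gain point near 0.28 Hz — below the 0.7 Hz heart-rate band
        — while passing the band itself nearly unattenuated.
    band
        Pass band in Hz for the zero-phase band-pass used by the
        chrominance path (and available for pulse post-filtering).
    filter_order
        Butterworth design order (applied forward-backward).
    """

    detrend_lambda: float = 300.0
    band: tuple[float, float] = (0.7, 3.0)
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.detrend_lambda <= 0:
            raise ValueError("detrend_lambda must be positive")
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi):
            raise ValueError(f"invalid band {self.band}")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass
class Whitening:
    """Centering + whitening transform z = V (x − mean).

    ``V`` is the symmetric inverse square root of the channel covariance,
    so the whitened traces have identity covariance, and ``V_inv`` maps
    back: x = V_inv z + mean.
    """

    V: np.ndarray
    V_inv: np.ndarray
    mean: np.ndarray


def detrend_smoothness_priors(x: TraceMatrix, lam: float | None = None) -> TraceMatrix:
    """Smoothness-priors detrending, applied per channel.

    Removes the low-frequency trend estimated by ridge-regularized
    second-difference smoothing: z_out = (I − (I + λ² D₂ᵀD₂)⁻¹) z, where
    D₂ is the (N−2)×N second-difference operator.  Acts as a gentle
    high-pass whose cutoff decreases with λ.
    """
    if lam is None:
        lam = PreprocessConfig().detrend_lambda
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    n = x.n
    if n < 3:
        raise ValueError("detrending needs at least 3 samples")
    trend = _smoothness_priors_trend(x.values, lam)
    return x.copy_with(x.values - trend)


def _smoothness_priors_trend(values: np.ndarray, lam: float) -> np.ndarray:
    """Solve (I + λ² D₂ᵀD₂) trend = values per row, via banded Cholesky."""
    n = values.shape[-1]
    # Pentadiagonal A = I + λ² D₂ᵀ D₂ in upper-banded storage for solveh_banded.
    l2 = lam * lam
    # Band diagonals of D₂ᵀD₂ for the (N−2)×N stencil [1, −2, 1]:
    main = np.ones(n)
    main[0] = main[-1] = 1.0
    main[1] = main[-2] = 5.0 if n >= 4 else main[1]
    main[2:-2] = 6.0
    if n == 3:
        main[:] = (1.0, 4.0, 1.0)
    elif n == 4:
        main[:] = (1.0, 5.0, 5.0, 1.0)
    off1 = np.full(n - 1, -4.0)
    off1[0] = off1[-1] = -2.0
    off2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0, 2:] = l2 * off2
    ab[1, 1:] = l2 * off1
    ab[2, :] = 1.0 + l2 * main
    trend = solveh_banded(ab, values.T, lower=False)
    return trend.T


def center(x: TraceMatrix) -> tuple[TraceMatrix, np.ndarray]:
    """Remove the per-channel mean; returns (centered traces, mean)."""
    mean = x.values.mean(axis=1)
    return x.copy_with(x.values - mean[:, None]), mean


def whiten(x: TraceMatrix) -> tuple[TraceMatrix, Whitening]:
    """Whiten centered traces to identity channel covariance.

    Uses the symmetric inverse square root of the biased sample covariance
    C = X Xᵀ / N (the same 1/N expectation convention as the unit-variance
    constraint downstream).  Raises on singular covariance.
    """
    vals = x.values
    n = x.n
    cov = vals @ vals.T / n
    evals, evecs = np.linalg.eigh(cov)
    tol = 1e-12 * max(evals.max(), 1.0)
    if np.any(evals <= tol):
        rank = int(np.sum(evals > tol))
        raise np.linalg.LinAlgError(
            f"channel covariance is singular (rank {rank} of 3); "
            "duplicated or constant channels cannot be whitened"
        )
    V = evecs @ np.diag(evals**-0.5) @ evecs.T
    V_inv = evecs @ np.diag(evals**0.5) @ evecs.T
    mean = vals.mean(axis=1)  # ≈ 0 for centered input; recorded for round-trip
    z = V @ (vals - mean[:, None])
    return x.copy_with(z), Whitening(V=V, V_inv=V_inv, mean=mean)


def bandpass(
    x: TraceMatrix,
    band: tuple[float, float] | None = None,
    order: int | None = None,
) -> TraceMatrix:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering removes phase distortion; DC is rejected by
    construction.
    """
    cfg = PreprocessConfig()
    band = band or cfg.band
    order = order or cfg.filter_order
    f_lo, f_hi = band
    nyq = x.fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band {band} invalid for fs={x.fs} (Nyquist {nyq})")
    sos_b, sos_a = butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass")
    filtered = filtfilt(sos_b, sos_a, x.values, axis=1)
    return x.copy_with(filtered)


def bandpass_signal(y: np.ndarray, fs: float, band=(0.7, 3.0), order: int = 4) -> np.ndarray:
    """Zero-phase band-pass for a 1-D signal (same design as :func:`bandpass`)."""
    f_lo, f_hi = band
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band {band} invalid for fs={fs}")
    b, a = butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass")
    return filtfilt(b, a, np.asarray(y, dtype=float))
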