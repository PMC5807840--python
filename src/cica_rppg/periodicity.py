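"""Autocorrelation-based periodicity score of a candidate pulse.

For a candidate pulse y = wᵀx of length N, the discrete autocorrelation
at non-negative lag k is r_k = Σ_j y_j (y lagged k)_j, with zero padding
on the left and r_0 forced to 0 (the lag-0 term is always large and
carries no periodicity information).  The periodicity score is the mean
of the squared autocorrelation, E{r²} = (1/N) Σ_k r_k².

Writing the lag as the shift matrix T_k (identity block in the top-right
corner), r_k = y T_k yᵀ = wᵀ (x T_k xᵀ) w is a quadratic form in w.  The
3×3 matrices M_k = x T_k xᵀ are precomputed once per analysis window by
sliding dot products (never materializing T_k), which makes the score and
its derivatives cheap to evaluate inside the optimizer:

    score(w) = (1/N) Σ_k (wᵀ M_k w)²
    grad     = (2/N) Σ_k r_k S_k w,            S_k = M_k + M_kᵀ
    hess     = (2/N) Σ_k (S_k w wᵀ S_k + r_k S_k)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cica_rppg.ingest import TraceMatrix


def lag_matrix(n: int, k: int) -> np.ndarray:
    """N×N shift matrix T_k: y @ T_k equals y lagged k with left zero-pad.

    Block form [[0_{N−k,k}, I_{N−k}], [0, 0]]; T_0 = I; T_k for k ≥ N is
    all-zero.  Exposed for small-N verification — the pipeline never
    builds these.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("lag k must be non-negative")
    t = np.zeros((n, n))
    if k < n:
        idx = np.arange(n - k)
        t[idx, idx + k] = 1.0
    return t


@dataclass
class AutocorrSeries:
    """Autocorrelation r_k for lags 0..N−1 with r_0 forced to zero."""

    r: np.ndarray

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.r))


def autocorrelation(y: np.ndarray) -> AutocorrSeries:
    """Discrete autocorrelation at lags 0..N−1, lag 0 zeroed.

    r_k = Σ_{j=k}^{N−1} y_j y_{j−k}, computed by direct sliding dot
    products (exact summation, no FFT).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y must be a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = len(y)
    full = np.correlate(y, y, mode="full")  # direct method, exact sums
    r = full[n - 1:].copy()  # non-negative lags
    r[0] = 0.0
    return AutocorrSeries(r=r)


@dataclass
class LagQuadratics:
    """Precomputed quadratic forms M_k = x T_k xᵀ for one analysis window.

    ``M`` has shape (N, 3, 3); M[0] is zeroed to implement the r_0 := 0
    convention, so r_k(w) = wᵀ M[k] w directly reproduces the lag series
    of y = wᵀx.  ``S`` caches M_k + M_kᵀ for the derivative formulas.
    """

    M: np.ndarray
    S: np.ndarray
    n: int

    @classmethod
    def from_traces(cls, x: TraceMatrix | np.ndarray) -> "LagQuadratics":
        vals = x.values if isinstance(x, TraceMatrix) else np.asarray(x, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != 3:
            raise ValueError(f"expected 3xN traces, got shape {vals.shape}")
        n = vals.shape[1]
        if n < 2:
            raise ValueError("need at least 2 samples")
        # M_k[a, b] = Σ_{j≥k} x_a[j] x_b[j−k]: the +k branch of the full
        # cross-correlation of channels a and b.
        m = np.empty((n, 3, 3))
        for a in range(3):
            for b in range(3):
                full = np.correlate(vals[a], vals[b], mode="full")
                m[:, a, b] = full[n - 1:]
        m[0] = 0.0  # lag-0 convention
        s = m + m.transpose(0, 2, 1)
        return cls(M=m, S=s, n=n)

    def r_of(self, w: np.ndarray) -> np.ndarray:
        """Autocorrelation series of y = wᵀx as quadratic forms in w."""
        w = np.asarray(w, dtype=float)
        return np.einsum("kab,a,b->k", self.M, w, w)


def periodicity_score(w: np.ndarray, lq: LagQuadratics) -> float:
    """Mean squared autocorrelation E{r²} of y = wᵀx (lag 0 excluded).

    Normalized by N (all lag slots, including the zeroed lag 0), which
    keeps the score roughly length-independent.
    """
    r = lq.r_of(w)
    return float(np.dot(r, r) / lq.n)


def periodicity_grad_hess(
    w: np.ndarray, lq: LagQuadratics
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and Hessian of :func:`periodicity_score` at w.

    With S_k = M_k + M_kᵀ and r_k = wᵀM_k w:
    grad = (2/N) Σ_k r_k S_k w; hess = (2/N) Σ_k (S_k w wᵀ S_k + r_k S_k).
    Verified against finite differences in the test suite.
    """
    w = np.asarray(w, dtype=float)
    r = lq.r_of(w)
    sw = lq.S @ w  # (N, 3)
    grad = (2.0 / lq.n) * (r @ sw)
    hess = (2.0 / lq.n) * (sw.T @ sw + np.einsum("k,kab->ab", r, lq.S))
    return grad, hess


def fibonacci_sphere(n_dirs: int) -> np.ndarray:
    """Quasi-uniform unit directions on S² (golden-angle spiral)."""
    i = np.arange(n_dirs, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_dirs
    phi = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def scan_weight_sphere(
    lq: LagQuadratics, n_dirs: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Periodicity score over quasi-uniform unit weight directions.

    The diagnostic view of E{r²} as a deformation of the unit sphere of
    weight vectors: the most periodic mixing direction shows up as the
    (antipodally symmetric) maximum.  Returns (directions (n,3), scores (n,)).
    """
    if n_dirs < 6:
        raise ValueError("n_dirs must be >= 6")
    dirs = fibonacci_sphere(n_dirs)
    # r for all directions at once: (n_dirs, N)
    r = np.einsum("kab,da,db->dk", lq.M, dirs, dirs)
    scores = np.sum(r * r, axis=1) / lq.n
    return dirs, scores
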