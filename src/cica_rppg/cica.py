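"""Constrained one-unit ICA for rPPG pulse extraction.

The demixing weight w (3-vector, whitened space) is found by maximizing
the FastICA negentropy approximation

    J(y) = ρ [E{G(y)} − E{G(v)}]²,   y = wᵀz,   v ~ N(0, 1),

with the log-cosh contrast G(u) = log cosh(a u)/a, 1 < a < 2, subject to

    g1(w) = ζ1 − E{r²}(w)        ≤ 0   (periodicity lower bound)
    g2(w) = ‖ŵ ∓ ŵ_chrom‖ − ζ2   ≤ 0   (chrominance proximity)
    h(w)  = E{y²} − 1            = 0   (unit variance; = wᵀw − 1 after
                                        whitening)

Two interchangeable backends solve the problem: a sequential-quadratic-
programming NLP solver fed the analytic gradients (the production path),
and an explicit augmented-Lagrangian outer loop with multiplier updates
μ_i ← max{0, μ_i + γ_i g_i(w)}, λ ← λ + β h(w).  Both are deterministic
given the same inputs and starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from cica_rppg.ingest import TraceMatrix
from cica_rppg.periodicity import LagQuadratics, periodicity_grad_hess, periodicity_score


# --------------------------------------------------------------------------
# Contrast function
# --------------------------------------------------------------------------

def g_function(u: np.ndarray | float, a: float = 1.5):
    """Log-cosh ICA contrast G(u) = log cosh(a u)/a and derivatives.

    Returns (G, G', G'') with G' = tanh(a u) and G'' = a (1 − tanh²(a u)).
    log cosh is evaluated overflow-free as |t| + log1p(e^{−2|t|}) − log 2.
    """
    if not (1.0 < a < 2.0):
        raise ValueError(f"contrast parameter a must lie in (1, 2), got {a}")
    u = np.asarray(u, dtype=float)
    t = a * u
    at = np.abs(t)
    logcosh = at + np.log1p(np.exp(-2.0 * at)) - math.log(2.0)
    g = logcosh / a
    th = np.tanh(t)
    g1 = th
    g2 = a * (1.0 - th * th)
    return g, g1, g2


def _expected_g_gauss(a: float, nodes: int = 200) -> float:
    """E{G(v)} for v ~ N(0,1) by Gauss–Hermite quadrature.

    log cosh grows linearly rather than polynomially, so convergence in
    the node count is slow: 200 nodes reach ~1e-14 absolute (64 nodes
    only ~2e-8).
    """
    x, w = np.polynomial.hermite.hermgauss(nodes)
    gv, _, _ = g_function(math.sqrt(2.0) * x, a)
    return float(np.sum(w * gv) / math.sqrt(math.pi))


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class ObjectiveSpec:
    """Negentropy objective parameters.

    ``EGv`` (the Gaussian reference expectation E{G(v)}) is computed once
    per ``a`` by 200-node Gauss–Hermite quadrature.
    """

    rho: float = 1.0
    a: float = 1.5
    EGv: float = field(default=None)

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not (1.0 < self.a < 2.0):
            raise ValueError(f"a must lie in (1, 2), got {self.a}")
        if self.EGv is None:
            self.EGv = _expected_g_gauss(self.a)


@dataclass
class ConstraintSpec:
    """Thresholds and anchor of the two inequality constraints.

    zeta1
        Lower bound on the periodicity score E{r²} (score units).
    zeta2
        Upper bound on the sign-aligned unit-sphere distance between the
        weight and the CHROM weight, in (0, 2].  ``inf`` disables the
        chrominance constraint (periodicity-only variant).
    w_chrom_white
        Unit-norm CHROM weights mapped into the whitened space.
    """

    zeta1: float
    zeta2: float
    w_chrom_white: np.ndarray

    def __post_init__(self) -> None:
        if self.zeta1 < 0:
            raise ValueError("zeta1 must be >= 0")
        if not (0 < self.zeta2):
            raise ValueError("zeta2 must be positive")
        self.w_chrom_white = np.asarray(self.w_chrom_white, dtype=float)
        nrm = np.linalg.norm(self.w_chrom_white)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("w_chrom_white must be a finite nonzero vector")
        self.w_chrom_white = self.w_chrom_white / nrm


@dataclass
class SolverConfig:
    """Backend selection and augmented-Lagrangian bookkeeping.

    ``backend`` is ``"nlp"`` (SQP with analytic gradients; default) or
    ``"augmented-lagrangian"`` (explicit outer loop with multiplier
    updates).  Penalties γ_i, β and initial multipliers μ_i, λ only
    matter for the latter.
    """

    backend: str = "nlp"
    mu: tuple[float, float] = (0.0, 0.0)
    lam: float = 0.0
    gamma: float = 10.0
    beta: float = 10.0
    max_iter: int = 200
    outer_iter: int = 15
    tol_kkt: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("nlp", "augmented-lagrangian"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("penalty parameters must be positive")
        if self.tol_kkt <= 0:
            raise ValueError("tol_kkt must be positive")


@dataclass
class CicaResult:
    """Solution of one window's constrained-ICA problem."""

    w_star: np.ndarray
    pulse: np.ndarray
    converged: bool
    objective: float
    g1: float
    g2: float
    h: float
    kkt: dict
    n_iter: int


# --------------------------------------------------------------------------
# Objective and constraints
# --------------------------------------------------------------------------

def negentropy(
    w: np.ndarray, z: np.ndarray, spec: ObjectiveSpec
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negentropy approximation J(w) with analytic gradient and Hessian.

    J = ρ Δ² with Δ = E{G(y)} − E{G(v)} and y = wᵀz; expectations are
    sample means over all N samples.  The exact sample derivatives are

        ∇J  = 2ρ Δ E{z G'(y)}
        ∇²J = 2ρ (E{z G'(y)} E{z G'(y)}ᵀ + Δ E{G''(y) z zᵀ}).
    """
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weight vector")
    y = w @ z
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite candidate pulse")
    g, g1, g2 = g_function(y, spec.a)
    delta = float(np.mean(g)) - spec.EGv
    q = z @ g1 / z.shape[1]  # E{z G'(y)}
    jval = spec.rho * delta * delta
    grad = 2.0 * spec.rho * delta * q
    zw = z * g2  # G''(y) broadcast over channels
    hess = 2.0 * spec.rho * (np.outer(q, q) + delta * (zw @ z.T) / z.shape[1])
    return jval, grad, hess


def constraint_g1(
    w: np.ndarray, lq: LagQuadratics, zeta1: float
) -> tuple[float, np.ndarray]:
    """Periodicity inequality g1 = ζ1 − E{r²}(w) (feasible when ≤ 0)."""
    grad_score, _ = periodicity_grad_hess(w, lq)
    return zeta1 - periodicity_score(w, lq), -grad_score


def constraint_g2(w: np.ndarray, spec: ConstraintSpec) -> tuple[float, np.ndarray]:
    """Chrominance inequality on the unit sphere, sign-aligned.

    g2 = min_± ‖ŵ ∓ ŵ_chrom‖ − ζ2 with ŵ = w/‖w‖; the sign alignment
    absorbs the ICA sign ambiguity.  At the singular point w ∝ ±w_chrom
    the subgradient 0 is returned.
    """
    w = np.asarray(w, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0.0:
        # distance from any unit vector to the sphere-projected origin is
        # ill-defined; treat as maximally distant with zero subgradient
        return 1.0 - spec.zeta2, np.zeros(3)
    what = w / norm
    wc = spec.w_chrom_white
    s = 1.0 if float(what @ wc) >= 0.0 else -1.0
    d = what - s * wc
    dist = float(np.linalg.norm(d))
    value = dist - spec.zeta2
    if dist < 1e-12:
        return value, np.zeros(3)
    # chain rule through the normalization: J_norm = (I − ŵŵᵀ)/‖w‖
    grad = (d - what * float(what @ d)) / (dist * norm)
    return value, grad


def constraint_h(w: np.ndarray, z: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Unit-variance equality h = E{y²} − 1 = wᵀw − 1 in whitened space."""
    w = np.asarray(w, dtype=float)
    return float(w @ w) - 1.0, 2.0 * w


def adaptive_zeta1(
    lq: LagQuadratics, w_chrom_white: np.ndarray, frac: float = 0.5
) -> float:
    """Periodicity threshold anchored to the CHROM direction's own score.

    ζ1 = frac × E{r²}(ŵ_chrom) tracks the signal scale of the current
    window and keeps the feasible set nonempty whenever the CHROM weights
    themselves carry periodic content (ŵ_chrom satisfies g2 and h by
    construction and g1 by a factor-1/frac margin).
    """
    wc = np.asarray(w_chrom_white, dtype=float)
    wc = wc / np.linalg.norm(wc)
    return frac * periodicity_score(wc, lq)


# --------------------------------------------------------------------------
# Solver backends
# --------------------------------------------------------------------------

def _as_array(z: TraceMatrix | np.ndarray) -> np.ndarray:
    return z.values if isinstance(z, TraceMatrix) else np.asarray(z, dtype=float)


def _solve_nlp(z, lq, obj, cons, cfg, w0):
    """SQP solve of min −J s.t. g1 ≤ 0, g2 ≤ 0, h = 0."""

    def fun(w):
        j, grad, _ = negentropy(w, z, obj)
        return -j, -grad

    constraints = [
        {
            "type": "eq",
            "fun": lambda w: np.array([constraint_h(w)[0]]),
            "jac": lambda w: constraint_h(w)[1][None, :],
        },
        {
            "type": "ineq",
            "fun": lambda w: np.array([-constraint_g1(w, lq, cons.zeta1)[0]]),
            "jac": lambda w: -constraint_g1(w, lq, cons.zeta1)[1][None, :],
        },
    ]
    if np.isfinite(cons.zeta2):
        constraints.append(
            {
                "type": "ineq",
                "fun": lambda w: np.array([-constraint_g2(w, cons)[0]]),
                "jac": lambda w: -constraint_g2(w, cons)[1][None, :],
            }
        )
    res = minimize(
        fun,
        w0,
        jac=True,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": cfg.max_iter, "ftol": 1e-10},
    )
    return res.x, bool(res.success), int(res.nit)


def _solve_augmented_lagrangian(z, lq, obj, cons, cfg, w0):
    """Explicit augmented-Lagrangian outer loop.

    Minimizes Φ(w) = −J + Σ_i (1/2γ_i)(max{0, μ_i + γ_i g_i}² − μ_i²)
                      + λ h + (β/2) h²
    and updates μ_i ← max{0, μ_i + γ_i g_i(w)}, λ ← λ + β h(w).
    """
    mu = list(cfg.mu)
    lam = cfg.lam
    gamma, beta = cfg.gamma, cfg.beta
    w = np.asarray(w0, dtype=float).copy()
    use_g2 = np.isfinite(cons.zeta2)
    n_inner = 0

    for _ in range(cfg.outer_iter):

        def phi(wv):
            j, jg, _ = negentropy(wv, z, obj)
            f, fg = -j, -jg
            gs = [constraint_g1(wv, lq, cons.zeta1)]
            if use_g2:
                gs.append(constraint_g2(wv, cons))
            for i, (gi, gi_grad) in enumerate(gs):
                t = mu[i] + gamma * gi
                if t > 0.0:
                    f += (t * t - mu[i] * mu[i]) / (2.0 * gamma)
                    fg = fg + t * gi_grad
                else:
                    f -= mu[i] * mu[i] / (2.0 * gamma)
            hv, hg = constraint_h(wv)
            f += lam * hv + 0.5 * beta * hv * hv
            fg = fg + (lam + beta * hv) * hg
            return f, fg

        res = minimize(phi, w, jac=True, method="BFGS",
                       options={"maxiter": cfg.max_iter, "gtol": 1e-8})
        w = res.x
        n_inner += int(res.nit)

        g1v, _ = constraint_g1(w, lq, cons.zeta1)
        g2v = constraint_g2(w, cons)[0] if use_g2 else -np.inf
        hv, _ = constraint_h(w)
        viol = max(g1v, g2v, abs(hv))
        mu[0] = max(0.0, mu[0] + gamma * g1v)
        if use_g2:
            mu[1] = max(0.0, mu[1] + gamma * g2v)
        lam = lam + beta * hv
        if viol <= cfg.tol_kkt:
            return w, True, n_inner
    return w, viol <= 10 * cfg.tol_kkt, n_inner


def solve_cica(
    z: TraceMatrix | np.ndarray,
    lq: LagQuadratics,
    objective: ObjectiveSpec,
    constraints: ConstraintSpec,
    cfg: SolverConfig | None = None,
    w_init: Optional[np.ndarray] = None,
) -> CicaResult:
    """Solve one window's constrained-ICA problem.

    ``z`` are whitened traces; ``lq`` the lag quadratics of the same
    window; ``w_init`` defaults to the whitened CHROM weights (warm
    starting with the previous window's solution is the pipeline's job).
    Never raises on solver failure mid-pipeline: an unconverged window is
    returned flagged, with best-effort weights.
    """
    cfg = cfg or SolverConfig()
    zv = _as_array(z)
    if not np.all(np.isfinite(zv)):
        raise ValueError("non-finite traces passed to solver")
    w0 = constraints.w_chrom_white if w_init is None else np.asarray(w_init, dtype=float)
    nrm = np.linalg.norm(w0)
    w0 = w0 / nrm if nrm > 0 else constraints.w_chrom_white

    order = (
        [_solve_nlp, _solve_augmented_lagrangian]
        if cfg.backend == "nlp"
        else [_solve_augmented_lagrangian, _solve_nlp]
    )
    w_best, ok, nit = w0, False, 0
    for backend in order:
        try:
            w_try, ok, nit = backend(zv, lq, objective, constraints, cfg, w0)
        except Exception:
            continue
        if np.all(np.isfinite(w_try)):
            w_best = w_try
        if ok:
            break

    # resolve ICA sign ambiguity toward the CHROM anchor
    if float(w_best @ constraints.w_chrom_white) < 0:
        w_best = -w_best

    g1v, g1g = constraint_g1(w_best, lq, constraints.zeta1)
    g2v = (
        constraint_g2(w_best, constraints)[0]
        if np.isfinite(constraints.zeta2)
        else float("-inf")
    )
    hv, _ = constraint_h(w_best)
    jval, jgrad, _ = negentropy(w_best, zv, objective)
    tol = cfg.tol_kkt
    feasible = g1v <= 1e2 * tol and g2v <= 1e2 * tol and abs(hv) <= 1e2 * tol
    converged = bool(ok and feasible)
    return CicaResult(
        w_star=w_best,
        pulse=w_best @ zv,
        converged=converged,
        objective=jval,
        g1=g1v,
        g2=g2v,
        h=hv,
        kkt={
            "g1": g1v,
            "g2": g2v,
            "h": hv,
            "grad_norm": float(np.linalg.norm(jgrad)),
        },
        n_iter=nit,
    )
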