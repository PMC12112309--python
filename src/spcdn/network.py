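"""Two-layer sparse/predictive coding (SPC) network dynamics.

The first layer computes the prediction error ``e = x - A s`` between the
input and the feedback reconstruction; the second layer integrates

    ds/dt = eta_s * (A^T e - H(s))

where ``H`` is the homeostasis function of the units.  Equilibria solve

    -A^T A s + A^T x = H(s),

geometrically the intersection of the line ``Y(s) = -A^T A s + A^T x`` with
``H(s)``; stability is governed by the Jacobian
``J(s) = -A^T A - diag(H'(s))``.  Since ``-A^T A`` is negative semidefinite
(negative definite for full-column-rank A), any monotonically increasing H
(``H' >= 0``) makes every equilibrium stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .homeostasis import (
    HomeostasisSpec,
    eval_derivative,
    eval_homeostasis,
    response_upper_bound,
)

__all__ = [
    "SPCNetwork",
    "IterationConfig",
    "ResponseResult",
    "EquilibriumResult",
    "NumericalFailure",
    "SolverFailure",
    "prediction_error",
    "iterate_responses",
    "solve_equilibrium",
    "jacobian",
    "stability_eigenvalues",
    "analytic_response_curve",
    "sparse_coding_cost",
]

# responses are clamped this far below a finite saturation during iteration
_SAT_MARGIN = 1e-9
# window length for the sign-alternation oscillation diagnostic
_OSC_WINDOW = 10


class NumericalFailure(RuntimeError):
    """Non-finite values encountered during response iteration."""


class SolverFailure(RuntimeError):
    """Equilibrium solver exhausted its budget; carries the best residual."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class SPCNetwork:
    """Two-layer SPC model: weights A (L x M), homeostasis, nonnegativity flag."""

    A: np.ndarray
    hspec: HomeostasisSpec
    nonnegative: bool = True

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D L x M matrix")
        if not np.all(np.isfinite(A)):
            raise ValueError("A contains non-finite entries")
        object.__setattr__(self, "A", A)

    @property
    def n_inputs(self) -> int:
        return self.A.shape[0]

    @property
    def n_units(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class IterationConfig:
    """Explicit-Euler settings for the response iteration.

    ``s_init`` may be a scalar fill value or a full response vector;
    0 is the neutral default, 1 reproduces the single-neuron convergence
    figures in which the response starts at 1.
    """

    eta_s: float = 0.002
    max_iter: int = 5000
    tol: float = 1e-8
    s_init: float | np.ndarray = 0.0
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if not self.eta_s > 0:
            raise ValueError("eta_s must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class ResponseResult:
    """Outcome of the response iteration for one input."""

    s_final: np.ndarray
    e_final: np.ndarray
    converged: bool
    oscillating: bool
    iterations_used: int
    clamp_count: int = 0
    trajectory: np.ndarray | None = None


@dataclass
class EquilibriumResult:
    """An equilibrium response with its local stability diagnosis."""

    s_eq: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    residual: float


def prediction_error(net: SPCNetwork, x, s) -> np.ndarray:
    """First-layer prediction error e = x - A s."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape[0] != net.n_inputs or s.shape[0] != net.n_units:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[0]} rows, s has {s.shape[0]}; "
            f"A is {net.A.shape}"
        )
    return x - net.A @ s


def _init_state(cfg: IterationConfig, shape: tuple[int, ...]) -> np.ndarray:
    s0 = np.asarray(cfg.s_init, dtype=float)
    if s0.ndim == 0:
        return np.full(shape, float(s0))
    if s0.shape != shape:
        raise ValueError(f"s_init has shape {s0.shape}, expected {shape}")
    return s0.copy()


def iterate_batch(
    net: SPCNetwork, X: np.ndarray, cfg: IterationConfig
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Vectorized response iteration for a batch of inputs (columns of X).

    Returns ``(S, converged_mask, iterations_used, clamp_count)``.  Used by the
    training loop, where per-input trajectories and oscillation diagnostics are
    not needed.
    """
    X = np.asarray(X, dtype=float)
    G = net.A.T @ net.A
    B = net.A.T @ X
    S = _init_state(cfg, B.shape)
    ub = response_upper_bound(net.hspec)
    cap = ub * (1.0 - _SAT_MARGIN) if np.isfinite(ub) else np.inf
    clamps = 0
    it = 0
    delta = np.full(B.shape[1], np.inf)
    for it in range(1, cfg.max_iter + 1):
        dS = cfg.eta_s * (B - G @ S - eval_homeostasis(net.hspec, S))
        S_new = S + dS
        if net.nonnegative:
            np.maximum(S_new, 0.0, out=S_new)
        if np.isfinite(cap):
            over = S_new > cap
            clamps += int(np.count_nonzero(over))
            np.minimum(S_new, cap, out=S_new)
        if not np.all(np.isfinite(S_new)):
            raise NumericalFailure(f"non-finite responses at iteration {it}")
        delta = np.abs(S_new - S).max(axis=0)
        S = S_new
        if delta.max() < cfg.tol:
            break
    converged = delta < cfg.tol
    return S, converged, it, clamps


def iterate_responses(net: SPCNetwork, x, cfg: IterationConfig | None = None) -> ResponseResult:
    """Integrate the response dynamics for a single input by explicit Euler.

    After each Euler step the state is rectified at 0 (when the network is
    nonnegative) and clamped just below a finite saturation bound of H, which
    would otherwise be overshot and leave the domain of H.  Convergence is
    declared when ``max |delta s| < tol``; oscillation is flagged when the sign
    of ``delta s`` alternated over the final 10 iterations for any unit.
    """
    if cfg is None:
        cfg = IterationConfig()
    x = np.asarray(x, dtype=float)
    G = net.A.T @ net.A
    b = net.A.T @ x
    s = _init_state(cfg, (net.n_units,))
    ub = response_upper_bound(net.hspec)
    cap = ub * (1.0 - _SAT_MARGIN) if np.isfinite(ub) else np.inf
    clamps = 0
    traj = [s.copy()] if cfg.record_trajectory else None
    # consecutive sign-alternation streak of delta-s, per unit
    streak = np.zeros(net.n_units, dtype=int)
    prev_sign = np.zeros(net.n_units, dtype=int)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        ds = cfg.eta_s * (b - G @ s - eval_homeostasis(net.hspec, s))
        s_new = s + ds
        if net.nonnegative:
            np.maximum(s_new, 0.0, out=s_new)
        if np.isfinite(cap):
            over = s_new > cap
            clamps += int(np.count_nonzero(over))
            np.minimum(s_new, cap, out=s_new)
        if not np.all(np.isfinite(s_new)):
            raise NumericalFailure(f"non-finite responses at iteration {it}")
        delta = s_new - s
        sign = np.sign(delta).astype(int)
        flip = (sign != 0) & (prev_sign != 0) & (sign == -prev_sign)
        streak = np.where(flip, streak + 1, 0)
        prev_sign = sign
        s = s_new
        if traj is not None:
            traj.append(s.copy())
        if np.abs(delta).max() < cfg.tol:
            converged = True
            break
    oscillating = bool(np.any(streak >= _OSC_WINDOW - 1))
    return ResponseResult(
        s_final=s,
        e_final=x - net.A @ s,
        converged=converged,
        oscillating=oscillating,
        iterations_used=it,
        clamp_count=clamps,
        trajectory=np.asarray(traj) if traj is not None else None,
    )


def jacobian(net: SPCNetwork, s) -> np.ndarray:
    """Jacobian of the response dynamics, J(s) = -A^T A - diag(H'(s))."""
    s = np.asarray(s, dtype=float)
    return -(net.A.T @ net.A) - np.diag(eval_derivative(net.hspec, s))


def stability_eigenvalues(net: SPCNetwork, s) -> tuple[np.ndarray, bool]:
    """Eigenvalues of J(s) and a flag that is True iff all real parts < 0.

    J is symmetric, so the spectrum is real and computed with ``eigvalsh``.
    A diverging H' at a domain boundary (e.g. a power-law prior with
    1 < alpha < 2 at s = 0) acts as an arbitrarily strong restoring force and
    is replaced by a large finite surrogate so the spectrum stays computable.
    """
    J = jacobian(net, s)
    J = np.nan_to_num(J, nan=-1e12, posinf=1e12, neginf=-1e12)
    eigs = np.linalg.eigvalsh(J)
    return eigs, bool(np.all(eigs < 0))


def _stationarity_residual(
    F: np.ndarray, s: np.ndarray, nonnegative: bool
) -> np.ndarray:
    """Componentwise KKT residual: F_i where s_i > 0, max(F_i, 0) at s_i = 0."""
    if not nonnegative:
        return F
    return np.where(s > 0, F, np.maximum(F, 0.0))


def solve_equilibrium(
    net: SPCNetwork, x, tol: float = 1e-10, max_newton: int = 200
) -> EquilibriumResult:
    """Solve -A^T A s + A^T x = H(s) for the equilibrium response.

    A damped Newton iteration on the inactive set (with nonnegativity treated
    as a complementarity condition: either ``s_i = 0`` with nonpositive drive,
    or the stationarity equation holds) is polished from a short projected-Euler
    warm start; if Newton stalls, a long-horizon projected-Euler fallback is
    used.  Raises :class:`SolverFailure` with the best residual if neither
    reaches ``tol``.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    x = np.asarray(x, dtype=float)
    G = net.A.T @ net.A
    b = net.A.T @ x
    ub = response_upper_bound(net.hspec)
    cap = ub * (1.0 - _SAT_MARGIN) if np.isfinite(ub) else np.inf

    def project(s: np.ndarray) -> np.ndarray:
        if net.nonnegative:
            s = np.maximum(s, 0.0)
        if np.isfinite(cap):
            s = np.minimum(s, cap)
        return s

    def F_of(s: np.ndarray) -> np.ndarray:
        return b - G @ s - eval_homeostasis(net.hspec, s)

    # warm start: a few hundred projected-Euler steps with a conservative rate;
    # steps are trust-region-limited so a steep saturating H cannot make the
    # state bounce between the cap and zero
    lam_max = float(np.linalg.eigvalsh(G)[-1]) if net.n_units else 0.0
    eta = 0.5 / (lam_max + 1.0)
    max_step = 0.02 * cap if np.isfinite(cap) else np.inf
    s = project(_init_state(IterationConfig(eta_s=eta), (net.n_units,)))
    for _ in range(300):
        ds = np.clip(eta * F_of(s), -max_step, max_step)
        s = project(s + ds)

    best_s = s
    best_res = float(np.abs(_stationarity_residual(F_of(s), s, net.nonnegative)).max())
    for _ in range(max_newton):
        F = F_of(s)
        res_vec = _stationarity_residual(F, s, net.nonnegative)
        res = float(np.abs(res_vec).max())
        if res < best_res:
            best_res, best_s = res, s
        if res <= tol:
            break
        if net.nonnegative:
            inactive = (s > 0) | (F > 0)
        else:
            inactive = np.ones(net.n_units, dtype=bool)
        if not np.any(inactive):
            break
        Hp = eval_derivative(net.hspec, s)
        # H' may be +inf at the domain edge (e.g. dn_equivalent at s=0);
        # a huge finite surrogate keeps the Newton system solvable
        Hp = np.nan_to_num(Hp, nan=1e12, posinf=1e12, neginf=-1e12)
        J = G[np.ix_(inactive, inactive)] + np.diag(Hp[inactive])
        try:
            d = np.linalg.solve(J, F[inactive])
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(40):
            cand = s.copy()
            cand[inactive] = s[inactive] + step * d
            cand = project(cand)
            if not np.all(np.isfinite(cand)):
                step *= 0.5
                continue
            cand_res = float(
                np.abs(_stationarity_residual(F_of(cand), cand, net.nonnegative)).max()
            )
            if cand_res < res:
                s = cand
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    else:
        pass

    res = float(np.abs(_stationarity_residual(F_of(s), s, net.nonnegative)).max())
    if res > tol:
        # long-horizon projected Euler fallback
        s = best_s.copy()
        for _ in range(200_000):
            s_new = project(s + np.clip(eta * F_of(s), -max_step, max_step))
            if np.abs(s_new - s).max() < tol * eta:
                s = s_new
                break
            s = s_new
        res = float(np.abs(_stationarity_residual(F_of(s), s, net.nonnegative)).max())
        if res < best_res:
            best_res, best_s = res, s
        if res > tol:
            raise SolverFailure(
                f"equilibrium residual {best_res:.3e} exceeds tol {tol:.1e}", best_res
            )

    eigs, stable = stability_eigenvalues(net, s)
    return EquilibriumResult(s_eq=s, eigenvalues=eigs, stable=stable, residual=res)


def analytic_response_curve(
    hspec: HomeostasisSpec, x_grid, xtol: float = 1e-12
) -> np.ndarray:
    """Analytic response-vs-input curve for the one-dimensional reduction.

    Assumes a single effective unit with ``A^T A = 1`` and ``A^T x = x``, so
    the equilibrium solves ``x - s = H(s)``, i.e. the intersection of the line
    ``Y(s) = -s + x`` with ``H(s)``.  Each grid point is solved by bracketed
    root finding on ``g(s) = s + H(s) - x`` over ``[0, s_M)``; a point with no
    bracket is marked NaN rather than raising.  Returns an (n, 2) array of
    (x, s_eq) pairs sorted by x.
    """
    x_grid = np.sort(np.asarray(x_grid, dtype=float))
    ub = response_upper_bound(hspec)
    hi_cap = ub * (1.0 - 1e-10) if np.isfinite(ub) else None
    out = np.empty((x_grid.size, 2))
    out[:, 0] = x_grid
    for k, x in enumerate(x_grid):
        g = lambda s: s + float(eval_homeostasis(hspec, np.asarray(s, dtype=float))) - x
        if g(0.0) >= 0.0:
            # drive too weak to lift the response off zero
            out[k, 1] = 0.0
            continue
        if hi_cap is not None:
            hi = hi_cap
            if g(hi) <= 0.0:
                # intersection indistinguishable from the asymptote
                out[k, 1] = hi
                continue
        else:
            hi = max(1.0, x)
            found = False
            for _ in range(60):
                if g(hi) > 0.0:
                    found = True
                    break
                hi *= 2.0
            if not found:
                out[k, 1] = np.nan
                continue
        out[k, 1] = brentq(g, 0.0, hi, xtol=xtol)
    return out


def sparse_coding_cost(net: SPCNetwork, x, s) -> float:
    """Sparse-coding energy 0.5 ||x - A s||^2 + lam * sum s^alpha / alpha.

    Only defined when the homeostasis is a power-law prior (``H = lam *
    s^(alpha-1)`` is the gradient of ``lam * s^alpha / alpha``), in which case
    the response dynamics are gradient descent on this cost.
    """
    if net.hspec.family != "power_prior":
        raise ValueError("sparse_coding_cost is defined for power_prior only")
    lam = net.hspec.params["lam"]
    alpha = net.hspec.params["alpha"]
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    recon = 0.5 * float(((x - net.A @ s) ** 2).sum())
    return recon + lam * float((s**alpha).sum()) / alpha
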