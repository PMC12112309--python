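"""Divisive normalization (DN) response models and Naka-Rushton fitting.

DN computes each unit's response as its (exponentiated) linear drive divided
by the pooled drive of the whole population,

    s_i^DN = gamma * (s_i^L)^n / (rho^n + sum_k (s_k^L)^n),    s_i^L = a_i^T x.

For a single unit with unit weight this reduces to the Naka-Rushton curve
``gamma x^n / (rho^n + x^n)``; for a population driven by a scaled stimulus
``x = alpha x0`` the response of any unit, as a function of the stimulus
strength alpha, again follows a Naka-Rushton curve with effective parameters
(``reduce_to_single``).  ``fit_naka_rushton`` estimates (gamma, rho, n) from a
measured contrast-response curve by bounded multi-start least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DNParams",
    "DNNetwork",
    "ReducedDN",
    "NakaRushtonFit",
    "dn_population_response",
    "naka_rushton",
    "invert_naka_rushton",
    "reduce_to_single",
    "fit_naka_rushton",
]


@dataclass(frozen=True)
class DNParams:
    """Naka-Rushton / divisive-normalization parameters.

    gamma : saturation response (> 0)
    rho   : semi-saturation input, where the response reaches gamma/2 (> 0)
    n     : steepness exponent (> 0)
    """

    gamma: float
    rho: float
    n: float

    def __post_init__(self) -> None:
        for name in ("gamma", "rho", "n"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"DNParams.{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class DNNetwork:
    """A bank of linear filters (columns of A) followed by divisive normalization."""

    A: np.ndarray  # L x M
    dn: DNParams

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[1] < 1:
            raise ValueError("A must be an L x M matrix with M >= 1")
        if not np.all(np.isfinite(A)):
            raise ValueError("A contains non-finite entries")
        object.__setattr__(self, "A", A)


@dataclass(frozen=True)
class ReducedDN:
    """Single-unit reduction of a multi-unit DN response to a scaled stimulus.

    For input x = alpha * x0 the response of the selected unit equals
    ``naka_rushton(alpha, DNParams(gamma0, rho0, n))``.
    """

    gamma0: float
    rho0: float
    n: float
    z: float  # population norm (sum_k (s_k^{L,0})^n)^(1/n)

    @property
    def dn(self) -> DNParams:
        return DNParams(self.gamma0, self.rho0, self.n)

    def response(self, alpha) -> np.ndarray | float:
        """Naka-Rushton response gamma0 * alpha^n / (rho0^n + alpha^n).

        Unlike :attr:`dn`, this remains valid when the unit has zero linear
        drive to the normalized stimulus (gamma0 = 0, response identically 0).
        """
        alpha = np.asarray(alpha, dtype=float)
        if np.any(alpha < 0):
            raise ValueError("stimulus strength alpha must be nonnegative")
        an = alpha**self.n
        out = self.gamma0 * an / (self.rho0**self.n + an)
        return out if out.ndim else float(out)


def _linear_drives(A: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (A.shape[0],):
        raise ValueError(f"input has shape {x.shape}, expected ({A.shape[0]},)")
    return A.T @ x


def dn_population_response(net: DNNetwork, x) -> np.ndarray:
    """Responses s^DN of all units of a DN network to input x.

    Negative linear drives are rectified at zero before exponentiation, so the
    response is well defined for non-integer exponents n.
    """
    sL = np.maximum(_linear_drives(net.A, np.asarray(x, dtype=float)), 0.0)
    gamma, rho, n = net.dn.gamma, net.dn.rho, net.dn.n
    pow_sL = sL**n
    return gamma * pow_sL / (rho**n + pow_sL.sum())


def naka_rushton(x, dn: DNParams):
    """Naka-Rushton response gamma * x^n / (rho^n + x^n) for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("naka_rushton requires nonnegative input")
    xn = x**dn.n
    out = dn.gamma * xn / (dn.rho**dn.n + xn)
    return out if out.ndim else float(out)


def invert_naka_rushton(s, dn: DNParams):
    """Input x producing response s: x = rho * (gamma/s - 1)^(-1/n), 0 < s < gamma."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0) or np.any(s >= dn.gamma):
        raise ValueError(
            f"invert_naka_rushton requires 0 < s < gamma = {dn.gamma}"
        )
    out = dn.rho * (dn.gamma / s - 1.0) ** (-1.0 / dn.n)
    return out if out.ndim else float(out)


def reduce_to_single(net: DNNetwork, x0, i: int) -> ReducedDN:
    """Reduce the DN response of unit ``i`` to a normalized stimulus ``x0``.

    With x = alpha*x0 and z = (sum_k (a_k^T x0)^n)^(1/n), the unit's response
    as a function of alpha is Naka-Rushton with gamma0 = gamma (a_i^T x0)^n / z^n
    and rho0 = rho / z.
    """
    sL0 = np.maximum(_linear_drives(net.A, np.asarray(x0, dtype=float)), 0.0)
    gamma, rho, n = net.dn.gamma, net.dn.rho, net.dn.n
    zn = float((sL0**n).sum())
    if zn <= 0.0:
        raise ValueError("degenerate stimulus: all linear drives are zero")
    z = zn ** (1.0 / n)
    gamma0 = gamma * float(sL0[i]) ** n / zn
    return ReducedDN(gamma0=gamma0, rho0=rho / z, n=n, z=z)


@dataclass(frozen=True)
class NakaRushtonFit:
    """Result of fitting a Naka-Rushton curve to a contrast-response curve."""

    params: DNParams | None
    sse: float
    r_squared: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def fit_naka_rushton(contrasts, responses) -> NakaRushtonFit:
    """Bounded multi-start least-squares fit of (gamma, rho, n).

    Bounds: gamma in (0, 2*max response], rho in (0, 2*max contrast],
    n in [0.5, 8].  Five deterministic starts from a coarse grid; the best
    final cost wins.  A flat (constant) response curve is flagged degenerate
    rather than fitted; non-convergence is flagged, not raised.
    """
    c = np.asarray(contrasts, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.ndim != 1 or c.shape != r.shape or c.size < 4:
        raise ValueError("need >= 4 matching (contrast, response) points")
    if np.any(c < 0) or np.any(r < 0):
        raise ValueError("contrasts and responses must be nonnegative")
    if np.unique(c).size != c.size:
        raise ValueError("contrasts must be distinct")
    rmax = float(r.max())
    if rmax == 0.0:
        raise ValueError("degenerate fit: all responses are zero")
    if np.ptp(r) < 1e-12 * rmax:
        return NakaRushtonFit(
            params=None, sse=0.0, r_squared=0.0, converged=False,
            degenerate=True, message="constant responses: saturation-only curve",
        )

    cmax = float(c.max())
    lo = np.array([1e-12, 1e-12, 0.5])
    hi = np.array([2.0 * rmax, 2.0 * cmax, 8.0])

    def resid(theta: np.ndarray) -> np.ndarray:
        gamma, rho, n = theta
        return gamma * c**n / (rho**n + c**n) - r

    # coarse deterministic starts spanning the plausible shapes
    starts = [
        (rmax, 0.5 * cmax, 2.0),
        (1.2 * rmax, 0.2 * cmax, 1.0),
        (1.5 * rmax, cmax, 4.0),
        (rmax, 0.05 * cmax, 2.0),
        (0.8 * rmax, 0.8 * cmax, 0.8),
    ]
    best = None
    for s0 in starts:
        theta0 = np.clip(np.asarray(s0, dtype=float), lo, hi)
        sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    sse = float(2.0 * best.cost)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    return NakaRushtonFit(
        params=DNParams(*[float(v) for v in best.x]),
        sse=sse,
        r_squared=r2,
        converged=bool(best.success),
        message=best.message,
    )
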