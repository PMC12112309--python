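"""Homeostasis functions that regulate sparse/predictive-coding responses.

In the two-layer sparse/predictive coding (SPC) model the response dynamics of
the second-layer units are ``ds/dt = eta_s * (A^T e - H(s))`` where ``H`` is a
per-unit self-regulation ("homeostasis") term equal to the scaled derivative of
the sparsity prior, ``H = lambda * Q'``.  The shape of ``H`` fully determines
the response nonlinearity of the network at equilibrium, so the families
implemented here span the classic sparse-coding priors, the function derived
from divisive normalization (whose equilibrium reproduces a Naka-Rushton
contrast-response curve exactly), and a concave-convex form that both supports
feature learning and saturates the response.

Families
--------
``zero``
    ``H(s) = 0`` — no regulation; the network relaxes to the least-squares
    solution.
``cauchy_prior``
    ``H(s) = lam * s / (1 + (s/sigma)^2)`` — derivative of a Cauchy-type
    log-prior; concave near the origin.
``gaussian_prior``
    ``H(s) = lam * s * exp(-(s/sigma)^2)``.
``power_prior``
    ``H(s) = lam * s^(alpha-1)`` for ``s >= 0``.  Feature learning requires
    ``1 <= alpha < 2``; a warning is emitted outside that range.
``dn_equivalent``
    ``H(s) = rho * (gamma/s - 1)^(-1/n) - s`` on the open interval
    ``0 <= s < gamma`` — the unique single-neuron homeostasis whose SPC
    equilibrium equals divisive normalization with parameters
    ``(gamma, rho, n)``.
``concave_convex``
    Two-branch form with a smooth turning point at ``x0``::

        H(s) = lam * 2*(s/x0) / (1 + (s/x0)^2)     for s <= x0
        H(s) = lam * exp(((s - x0)/sigma)^n)       for s >  x0

    Concave below ``x0`` (enables Gabor learning), convex and rapidly growing
    above it (produces contrast saturation); both branches equal ``lam`` at
    ``x0`` and for ``n >= 2`` the derivative vanishes there, so the transition
    is continuous and smooth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .normalization import DNParams

__all__ = [
    "FAMILIES",
    "HomeostasisSpec",
    "eval_homeostasis",
    "eval_derivative",
    "response_upper_bound",
    "homeostasis_from_dn",
]

#: family name -> required parameter names
FAMILIES: dict[str, tuple[str, ...]] = {
    "zero": (),
    "cauchy_prior": ("lam", "sigma"),
    "gaussian_prior": ("lam", "sigma"),
    "power_prior": ("lam", "alpha"),
    "dn_equivalent": ("gamma", "rho", "n"),
    "concave_convex": ("lam", "x0", "sigma", "n"),
}

# margin below the vertical asymptote treated as out of domain
_DOMAIN_GUARD = 1e-12


class DomainError(ValueError):
    """Response value outside the valid domain of a homeostasis function."""


@dataclass(frozen=True)
class HomeostasisSpec:
    """A parameterized homeostasis function H(.) shared by all units.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Exactly the named real parameters the family requires:
        ``lam`` (penalty scale, >= 0), ``sigma`` (width, > 0),
        ``alpha`` (power exponent), ``gamma`` (saturation, > 0),
        ``rho`` (semi-saturation, > 0), ``n`` (steepness exponent, > 0),
        ``x0`` (concave-to-convex turning point, > 0).
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown homeostasis family {self.family!r}; "
                f"expected one of {sorted(FAMILIES)}"
            )
        required = set(FAMILIES[self.family])
        given = set(self.params)
        if given != required:
            raise ValueError(
                f"family {self.family!r} requires parameters {sorted(required)}, "
                f"got {sorted(given)}"
            )
        p = self.params
        for name, bound_ok, desc in (
            ("lam", lambda v: v >= 0, "lam must be >= 0"),
            ("sigma", lambda v: v > 0, "sigma must be > 0"),
            ("gamma", lambda v: v > 0, "gamma must be > 0"),
            ("rho", lambda v: v > 0, "rho must be > 0"),
            ("n", lambda v: v > 0, "n must be > 0"),
            ("x0", lambda v: v > 0, "x0 must be > 0"),
        ):
            if name in p and not bound_ok(float(p[name])):
                raise ValueError(f"invalid {self.family} spec: {desc} (got {p[name]})")
        if self.family == "power_prior":
            alpha = float(p["alpha"])
            if not (1.0 <= alpha < 2.0):
                warnings.warn(
                    f"power_prior with alpha={alpha} is outside [1, 2); "
                    "feature learning requires 1 <= alpha < 2",
                    UserWarning,
                    stacklevel=3,
                )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        """Flat table {family, params} suitable for JSON/TOML/HDF5 attrs."""
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, table: dict) -> "HomeostasisSpec":
        return cls(family=table["family"], params={k: float(v) for k, v in table["params"].items()})


def _as_array(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("response vector contains non-finite values")
    return s


# families whose H extends naturally (as an odd function) to negative s;
# used by dynamics with the nonnegativity constraint switched off
_ODD_FAMILIES = frozenset({"zero", "cauchy_prior", "gaussian_prior"})


def _check_domain(spec: HomeostasisSpec, s: np.ndarray) -> None:
    if spec.family not in _ODD_FAMILIES and np.any(s < 0):
        i = int(np.argmin(s))
        raise DomainError(f"negative response s[{i}]={np.asarray(s).flat[i]}")
    if spec.family == "dn_equivalent":
        gamma = spec.params["gamma"]
        bad = s >= gamma * (1.0 - _DOMAIN_GUARD)
        if np.any(bad):
            i = int(np.argmax(bad))
            val = float(np.asarray(s).flat[i])
            raise DomainError(
                f"response component {i} = {val} is at or beyond the "
                f"saturation gamma = {gamma}; dn_equivalent H is defined for s < gamma"
            )


def eval_homeostasis(spec: HomeostasisSpec, s) -> np.ndarray:
    """Evaluate H(s) elementwise.

    ``s`` must be nonnegative and, for the ``dn_equivalent`` family, strictly
    below the saturation ``gamma`` (a :class:`DomainError` is raised otherwise
    rather than clamping — keeping iterates inside the domain is the dynamics
    integrator's job).
    """
    s = _as_array(s)
    _check_domain(spec, s)
    p = spec.params
    fam = spec.family
    if fam == "zero":
        return np.zeros_like(s)
    if fam == "cauchy_prior":
        u = s / p["sigma"]
        return p["lam"] * s / (1.0 + u * u)
    if fam == "gaussian_prior":
        u = s / p["sigma"]
        return p["lam"] * s * np.exp(-u * u)
    if fam == "power_prior":
        alpha = p["alpha"]
        with np.errstate(divide="ignore"):
            out = p["lam"] * np.power(s, alpha - 1.0)
        # s^0 == 1 at s=0 for alpha=1 (the L1 prior's constant derivative)
        if alpha == 1.0:
            out = np.full_like(s, p["lam"])
        return out
    if fam == "dn_equivalent":
        gamma, rho, n = p["gamma"], p["rho"], p["n"]
        flat = np.atleast_1d(s).astype(float)
        out = np.zeros_like(flat)
        pos = flat > 0
        g = gamma / flat[pos] - 1.0
        out[pos] = rho * np.power(g, -1.0 / n) - flat[pos]
        return out.reshape(s.shape)
    if fam == "concave_convex":
        lam, x0, sigma, n = p["lam"], p["x0"], p["sigma"], p["n"]
        u = s / x0
        concave = lam * 2.0 * u / (1.0 + u * u)
        v = (s - x0) / sigma
        with np.errstate(over="ignore"):
            convex = lam * np.exp(np.where(v > 0, v, 0.0) ** n)
        return np.where(s <= x0, concave, convex)
    raise AssertionError(fam)  # pragma: no cover


def eval_derivative(spec: HomeostasisSpec, s) -> np.ndarray:
    """Analytic elementwise derivative H'(s), needed by the Jacobian."""
    s = _as_array(s)
    _check_domain(spec, s)
    p = spec.params
    fam = spec.family
    if fam == "zero":
        return np.zeros_like(s)
    if fam == "cauchy_prior":
        u2 = (s / p["sigma"]) ** 2
        return p["lam"] * (1.0 - u2) / (1.0 + u2) ** 2
    if fam == "gaussian_prior":
        u2 = (s / p["sigma"]) ** 2
        return p["lam"] * np.exp(-u2) * (1.0 - 2.0 * u2)
    if fam == "power_prior":
        alpha = p["alpha"]
        if alpha == 1.0:
            return np.zeros_like(s)
        with np.errstate(divide="ignore"):
            return p["lam"] * (alpha - 1.0) * np.power(s, alpha - 2.0)
    if fam == "dn_equivalent":
        gamma, rho, n = p["gamma"], p["rho"], p["n"]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = gamma / s - 1.0
            return rho * gamma / (n * s * s) * np.power(g, -1.0 / n - 1.0) - 1.0
    if fam == "concave_convex":
        lam, x0, sigma, n = p["lam"], p["x0"], p["sigma"], p["n"]
        u2 = (s / x0) ** 2
        concave = lam * (2.0 / x0) * (1.0 - u2) / (1.0 + u2) ** 2
        v = np.where(s > x0, (s - x0) / sigma, 0.0)
        with np.errstate(over="ignore"):
            convex = lam * (n / sigma) * v ** (n - 1.0) * np.exp(v**n)
        return np.where(s <= x0, concave, convex)
    raise AssertionError(fam)  # pragma: no cover


def response_upper_bound(spec: HomeostasisSpec) -> float:
    """Location of the vertical asymptote of H, or +inf if H is finite.

    A diverging H caps the equilibrium response: the intersection of the
    network line Y(s) with H(s) can never cross the asymptote, so the value
    returned here is the analytic upper bound on the response.
    """
    if spec.family == "dn_equivalent":
        return float(spec.params["gamma"])
    return math.inf


def homeostasis_from_dn(dn: "DNParams") -> HomeostasisSpec:
    """Homeostasis function whose single-neuron SPC equilibrium equals DN.

    Inverting the Naka-Rushton response ``s = gamma x^n / (rho^n + x^n)``
    and substituting into the equilibrium condition ``x - s = H(s)`` yields
    ``H(s) = rho (gamma/s - 1)^(-1/n) - s`` for ``0 < s < gamma``.
    """
    return HomeostasisSpec(
        "dn_equivalent",
        {"gamma": float(dn.gamma), "rho": float(dn.rho), "n": float(dn.n)},
    )
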