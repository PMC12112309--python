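"""Receptive-field analysis and the contrast-response protocol.

After training, each unit's receptive field (a column of A reshaped to the
patch) is fitted with a Gabor filter; units whose relative fitting error is
below 40% and whose envelope lies well inside the patch are selected as
model simple cells.  For each selected cell, sinusoidal gratings at the
preferred orientation and spatial frequency (and at a suboptimal orientation,
30 degrees away by default) are presented over a range of contrasts and
spatial phases; the converged response, averaged over phases, gives the
contrast-response curve, which is then fitted with the single-unit divisive
normalization (Naka-Rushton) equation.  The ratio of suboptimal to optimal
response at the highest contrast is the cell's suboptimal scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .network import IterationConfig, SPCNetwork, iterate_batch
from .normalization import NakaRushtonFit, fit_naka_rushton
from .stimuli import FLATTEN_ORDER, GratingSpec, make_grating

__all__ = [
    "GaborFit",
    "ContrastCurve",
    "AnalysisConfig",
    "AnalysisReport",
    "fit_gabor",
    "select_cells",
    "contrast_response_curve",
    "suboptimal_scaling",
    "analyze_model",
]


@dataclass(frozen=True)
class GaborFit:
    """A fitted Gabor filter and its relative fitting error.

    ``fit_error = ||rf - gabor||_2 / ||rf||_2``; orientation and phase are in
    degrees, spatial frequency in cycles/patch, envelope SDs in pixels
    (parallel = along the modulation direction, perpendicular = along the
    bar axis).
    """

    center: tuple[float, float]
    orientation: float
    spatial_frequency: float
    phase: float
    envelope_sd: tuple[float, float]
    amplitude: float
    fit_error: float


@dataclass
class ContrastCurve:
    """Phase-averaged contrast-response curve of one model cell."""

    contrasts: np.ndarray
    responses: np.ndarray
    orientation_offset: float = 0.0
    dn_fit: NakaRushtonFit | None = None
    normalized: bool = False
    all_converged: bool = True
    converged: np.ndarray | None = None  # per contrast

    def normalized_copy(self) -> "ContrastCurve":
        peak = self.responses.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero curve")
        return ContrastCurve(
            contrasts=self.contrasts.copy(),
            responses=self.responses / peak,
            orientation_offset=self.orientation_offset,
            dn_fit=self.dn_fit,
            normalized=True,
            all_converged=self.all_converged,
            converged=self.converged,
        )


def _gabor_patch(edge: int, theta: np.ndarray | float, params: np.ndarray) -> np.ndarray:
    """Evaluate a Gabor on an edge x edge grid.

    params = (cx, cy, theta_deg, sf, phase_deg, sd_par, sd_perp, amp); the
    modulation runs along (cos theta, sin theta), matching the grating
    convention.
    """
    cx, cy, theta_deg, sf, phase_deg, sd_par, sd_perp, amp = params
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phase_deg)
    u = np.arange(edge)[:, None] - cx
    v = np.arange(edge)[None, :] - cy
    d_par = u * np.cos(th) + v * np.sin(th)
    d_perp = -u * np.sin(th) + v * np.cos(th)
    envelope = np.exp(-0.5 * (d_par / sd_par) ** 2 - 0.5 * (d_perp / sd_perp) ** 2)
    carrier = np.cos(2.0 * np.pi * sf * d_par / edge + ph)
    return amp * envelope * carrier


def _dominant_frequency(rf: np.ndarray) -> float:
    """Peak spatial frequency (cycles/patch) of the rf's power spectrum."""
    edge = rf.shape[0]
    P = np.abs(np.fft.fft2(rf)) ** 2
    fx = np.fft.fftfreq(edge) * edge  # cycles per patch
    FX, FY = np.meshgrid(fx, fx, indexing="ij")
    F = np.hypot(FX, FY)
    P[0, 0] = 0.0
    return max(float(F.flat[np.argmax(P)]), 0.5)


def fit_gabor(rf: np.ndarray) -> GaborFit:
    """Nonlinear least-squares Gabor fit of a receptive field.

    Deterministic multi-start: 8 orientation starts on a uniform grid, center
    initialized at the energy centroid, spatial frequency at the spectral
    peak.  The best final cost wins.
    """
    rf = np.asarray(rf, dtype=float)
    if rf.ndim != 2 or rf.shape[0] != rf.shape[1]:
        raise ValueError("rf must be a square 2-D matrix")
    norm = float(np.linalg.norm(rf))
    if norm == 0.0:
        raise ValueError("cannot fit a Gabor to an identically zero rf")
    edge = rf.shape[0]
    energy = rf**2
    idx = np.arange(edge)
    cx0 = float((energy.sum(axis=1) * idx).sum() / energy.sum())
    cy0 = float((energy.sum(axis=0) * idx).sum() / energy.sum())
    sf0 = _dominant_frequency(rf)
    amp0 = float(rf.flat[np.argmax(np.abs(rf))])

    lo = np.array([-2.0, -2.0, -360.0, 0.5, -720.0, 0.5, 0.5, -10 * abs(amp0) - 1e-9])
    hi = np.array(
        [edge + 2.0, edge + 2.0, 720.0, edge / 2.0, 720.0, edge, edge, 10 * abs(amp0) + 1e-9]
    )

    def resid(p: np.ndarray) -> np.ndarray:
        return (_gabor_patch(edge, p[2], p) - rf).ravel() / norm

    best = None
    for theta0 in np.arange(0.0, 180.0, 22.5):
        p0 = np.clip(
            np.array([cx0, cy0, theta0, sf0, 0.0, edge / 6.0, edge / 6.0, amp0]),
            lo,
            hi,
        )
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    p = best.x
    err = float(np.linalg.norm(resid(p)))
    return GaborFit(
        center=(float(p[0]), float(p[1])),
        orientation=float(p[2]) % 180.0,
        spatial_frequency=float(p[3]),
        phase=float(p[4]) % 360.0,
        envelope_sd=(float(p[5]), float(p[6])),
        amplitude=float(p[7]),
        fit_error=err,
    )


def select_cells(
    fits: list[GaborFit],
    patch_edge: int,
    error_threshold: float = 0.40,
    margin: float = 3.0,
) -> list[int]:
    """Indices of well-fit, centrally located cells.

    A cell is kept when its Gabor fit error is below ``error_threshold``, its
    center lies in ``[margin, patch_edge - margin]`` in both coordinates, and
    the envelope (center +/- 2 SD, using the larger SD) is contained in the
    patch.
    """
    keep = []
    for i, f in enumerate(fits):
        if f.fit_error >= error_threshold:
            continue
        cx, cy = f.center
        if not (margin <= cx <= patch_edge - margin and margin <= cy <= patch_edge - margin):
            continue
        sd = 2.0 * max(f.envelope_sd)
        if cx - sd < 0 or cx + sd > patch_edge or cy - sd < 0 or cy + sd > patch_edge:
            continue
        keep.append(i)
    return keep


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the contrast-response pipeline."""

    contrasts: tuple[float, ...] = (0.02, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)
    n_phases: int = 16
    orientation_offset: float = 30.0
    error_threshold: float = 0.40
    margin: float = 3.0
    normalize: bool = False
    iteration: IterationConfig = field(
        default_factory=lambda: IterationConfig(eta_s=0.005, max_iter=6000, tol=1e-8)
    )

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.n_phases) * 360.0 / self.n_phases


def contrast_response_curve(
    net: SPCNetwork,
    unit: int,
    prefs: GaborFit,
    cfg: AnalysisConfig,
    orientation_offset: float = 0.0,
) -> ContrastCurve:
    """Phase-averaged contrast-response curve of one unit.

    For each contrast, gratings at the unit's preferred orientation (plus
    ``orientation_offset``) and spatial frequency are presented at every
    phase; the unit's converged response is averaged over phases.
    Non-convergence at a contrast is flagged per point, not raised.
    """
    edge = int(round(np.sqrt(net.n_inputs)))
    if edge * edge != net.n_inputs:
        raise ValueError("network input dimension is not a square patch")
    contrasts = np.asarray(cfg.contrasts, dtype=float)
    phases = cfg.phases
    specs = [
        GratingSpec(
            edge=edge,
            contrast=float(c),
            orientation=prefs.orientation + orientation_offset,
            spatial_frequency=prefs.spatial_frequency,
            phase=float(p),
        )
        for c in contrasts
        for p in phases
    ]
    X = np.column_stack([make_grating(sp) for sp in specs])
    S, conv, _, _ = iterate_batch(net, X, cfg.iteration)
    resp = S[unit].reshape(contrasts.size, phases.size)
    conv = conv.reshape(contrasts.size, phases.size)
    responses = resp.mean(axis=1)
    conv_per_contrast = conv.all(axis=1)
    curve = ContrastCurve(
        contrasts=contrasts,
        responses=responses,
        orientation_offset=orientation_offset,
        all_converged=bool(conv_per_contrast.all()),
        converged=conv_per_contrast,
    )
    return curve


def suboptimal_scaling(curve_opt: ContrastCurve, curve_sub: ContrastCurve) -> float:
    """Ratio of suboptimal to optimal mean response at the highest contrast."""
    if curve_opt.contrasts.shape != curve_sub.contrasts.shape or not np.allclose(
        curve_opt.contrasts, curve_sub.contrasts
    ):
        raise ValueError("curves must share the same contrast grid")
    i = int(np.argmax(curve_opt.contrasts))
    top_opt = float(curve_opt.responses[i])
    if top_opt <= 0:
        raise ValueError("optimal curve has zero response at the top contrast")
    return float(curve_sub.responses[i]) / top_opt


@dataclass
class AnalysisReport:
    """End-to-end analysis of a trained network."""

    fits: list[GaborFit]
    selected: list[int]
    curves_optimal: dict[int, ContrastCurve]
    curves_suboptimal: dict[int, ContrastCurve]
    scaling: dict[int, float]


def analyze_model(net: SPCNetwork, cfg: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full receptive-field and contrast-response pipeline.

    Fits a Gabor to every unit's receptive field, selects well-fit central
    cells, measures optimal and suboptimal contrast-response curves, fits the
    Naka-Rushton equation to each optimal curve, and computes the suboptimal
    scaling of every selected cell.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    edge = int(round(np.sqrt(net.n_inputs)))
    fits = [
        fit_gabor(net.A[:, i].reshape(edge, edge, order=FLATTEN_ORDER))
        for i in range(net.n_units)
    ]
    selected = select_cells(fits, edge, cfg.error_threshold, cfg.margin)
    curves_opt: dict[int, ContrastCurve] = {}
    curves_sub: dict[int, ContrastCurve] = {}
    scaling: dict[int, float] = {}
    for i in selected:
        opt = contrast_response_curve(net, i, fits[i], cfg, orientation_offset=0.0)
        sub = contrast_response_curve(
            net, i, fits[i], cfg, orientation_offset=cfg.orientation_offset
        )
        if opt.responses.max() > 0 and np.ptp(opt.responses) > 0:
            opt.dn_fit = fit_naka_rushton(opt.contrasts, opt.responses)
        if sub.responses.max() > 0 and np.ptp(sub.responses) > 0:
            sub.dn_fit = fit_naka_rushton(sub.contrasts, sub.responses)
        if opt.responses.max() > 0:
            scaling[i] = suboptimal_scaling(opt, sub)
        if cfg.normalize and opt.responses.max() > 0:
            # per-cell normalization to a peak optimal response of 1; the
            # suboptimal curve shares the optimal curve's scale factor
            peak = opt.responses.max()
            sub = ContrastCurve(
                contrasts=sub.contrasts,
                responses=sub.responses / peak,
                orientation_offset=sub.orientation_offset,
                dn_fit=sub.dn_fit,
                normalized=True,
                all_converged=sub.all_converged,
                converged=sub.converged,
            )
            opt = opt.normalized_copy()
        curves_opt[i] = opt
        curves_sub[i] = sub
    return AnalysisReport(
        fits=fits,
        selected=selected,
        curves_optimal=curves_opt,
        curves_suboptimal=curves_sub,
        scaling=scaling,
    )
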