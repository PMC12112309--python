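"""Synthetic naturalistic images, whitening, patch sampling, and gratings.

The synthetic generator emulates the statistics of pre-processed natural
scenes that sparse-coding studies train on: an approximately 1/f amplitude
spectrum (power-spectrum slope near -2), heavy-tailed pixel histograms
(excess kurtosis > 0), and an abundance of oriented edge/bar structure.  It
draws many randomly placed, oriented, elongated Gaussian bars with
heavy-tailed amplitudes over a 1/f-filtered noise floor.  The generator is
deterministic given its seed, so training runs are reproducible without any
external image files.

Whitening follows the classic radial filter with a low-pass guard,
``W(f) = f * exp(-(f/f0)^4)`` with ``f0 = 0.4 * Nyquist``, applied in the
Fourier domain to zero-mean images.  Patches are flattened column-major
(Fortran order); every module in the package shares this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ImageSet",
    "GratingSpec",
    "generate_naturalistic_images",
    "whiten_images",
    "sample_patches",
    "make_grating",
    "grating_sweep",
]

#: flattening order for 2-D patches -> vectors, shared across the package
FLATTEN_ORDER = "F"


@dataclass(frozen=True)
class ImageSet:
    """A list of same-sized square grayscale images plus provenance."""

    images: tuple[np.ndarray, ...]
    provenance: dict = field(default_factory=dict)
    whitened: bool = False

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("ImageSet requires at least one image")
        edge = self.images[0].shape
        for im in self.images:
            if im.shape != edge or im.ndim != 2 or im.shape[0] != im.shape[1]:
                raise ValueError("all images must be square and of identical size")
            if not np.all(np.isfinite(im)):
                raise ValueError("image contains non-finite values")

    @property
    def edge(self) -> int:
        return self.images[0].shape[0]


@dataclass(frozen=True)
class GratingSpec:
    """A sinusoidal grating patch specification.

    ``contrast`` is the grating amplitude on the (whitened, unitless) model
    input scale and plays the role of the input-strength scalar multiplying a
    normalized stimulus; ``spatial_frequency`` is in cycles per patch;
    ``orientation`` and ``phase`` are in degrees.
    """

    edge: int
    contrast: float
    orientation: float
    spatial_frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if not self.spatial_frequency > 0:
            raise ValueError("spatial_frequency must be > 0")


def _one_over_f_noise(rng: np.random.Generator, edge: int) -> np.ndarray:
    """Gaussian noise filtered to a 1/f amplitude spectrum, unit variance."""
    white = rng.standard_normal((edge, edge))
    fx = np.fft.fftfreq(edge)
    fy = np.fft.fftfreq(edge)
    f = np.hypot(*np.meshgrid(fx, fy, indexing="ij"))
    f[0, 0] = np.inf  # kill DC
    filt = 1.0 / f
    im = np.fft.ifft2(np.fft.fft2(white) * filt).real
    return im / im.std()


def _add_bar(
    im: np.ndarray,
    rng: np.random.Generator,
    amp_scale: float,
) -> None:
    """Draw one oriented elongated Gaussian stroke in place.

    Strokes are short (1.5-6 px) and thin (0.4-1.2 px): localized oriented
    structure at roughly the scale of V1-model receptive fields, rather than
    image-spanning contours, mirroring the fine edge content that dominates
    pre-processed natural scenes at patch scale.
    """
    edge = im.shape[0]
    cx, cy = rng.uniform(0, edge, size=2)
    theta = rng.uniform(0, np.pi)
    length = rng.uniform(1.5, 6.0)
    thickness = rng.uniform(0.4, 1.2)
    # heavy-tailed amplitude: Laplace gives sparse strong edges
    amp = amp_scale * rng.laplace()
    half = int(np.ceil(length + 4 * thickness))
    x0, x1 = max(0, int(cx) - half), min(edge, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(edge, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)[:, None] - cx
    ys = np.arange(y0, y1)[None, :] - cy
    c, s = np.cos(theta), np.sin(theta)
    d_par = xs * c + ys * s
    d_perp = -xs * s + ys * c
    im[x0:x1, y0:y1] += amp * np.exp(
        -((d_perp / thickness) ** 2) - (d_par / length) ** 2
    )


def generate_naturalistic_images(
    count: int = 10,
    edge: int = 128,
    seed: int = 0,
    bars_per_image: int = 600,
    noise_floor: float = 0.35,
) -> ImageSet:
    """Generate a deterministic set of synthetic naturalistic images.

    Each image is a 1/f-noise floor plus ``bars_per_image`` oriented bars with
    Laplace-distributed amplitudes, giving an approximately 1/f spectrum and
    leptokurtic (excess kurtosis > 0) pixel statistics.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if edge < 64:
        raise ValueError("edge must be >= 64")
    rng = np.random.default_rng(seed)
    images = []
    for _ in range(count):
        im = noise_floor * _one_over_f_noise(rng, edge)
        for _ in range(bars_per_image):
            _add_bar(im, rng, amp_scale=1.0)
        im -= im.mean()
        im /= im.std()
        images.append(im)
    return ImageSet(
        images=tuple(images),
        provenance={
            "kind": "synthetic",
            "seed": seed,
            "count": count,
            "edge": edge,
            "bars_per_image": bars_per_image,
            "noise_floor": noise_floor,
        },
        whitened=False,
    )


def whitening_filter(edge: int, f0_frac: float = 0.4) -> np.ndarray:
    """Radial whitening filter with low-pass guard, peak-normalized.

    ``W(f) = f * exp(-(f/f0)^4)`` with ``f0 = f0_frac * Nyquist``; the filter
    is scaled so its maximum gain is 1, which fixes the output scale without
    any data-dependent normalization (keeping the operation linear).
    """
    fx = np.fft.fftfreq(edge)
    f = np.hypot(*np.meshgrid(fx, fx, indexing="ij"))
    f0 = f0_frac * 0.5
    W = f * np.exp(-((f / f0) ** 4))
    return W / W.max()


def whiten_images(imset: ImageSet, f0_frac: float = 0.4) -> ImageSet:
    """Whiten a set of images with the radial low-pass-guarded filter.

    Images are made zero-mean and filtered in the Fourier domain; the
    operation is linear in the input images.  Whitening an already-whitened
    set raises.
    """
    if imset.whitened:
        raise ValueError("ImageSet is already whitened")
    W = whitening_filter(imset.edge, f0_frac)
    out = []
    for im in imset.images:
        im0 = im - im.mean()
        out.append(np.fft.ifft2(np.fft.fft2(im0) * W).real)
    prov = dict(imset.provenance)
    prov["whitening_f0_frac"] = f0_frac
    return ImageSet(images=tuple(out), provenance=prov, whitened=True)


def sample_patches(
    imset: ImageSet, patch_edge: int, count: int, seed: int = 0
) -> np.ndarray:
    """Sample ``count`` random square patches, flattened to an L x count batch.

    Top-left corners are uniform over positions keeping the patch fully inside
    the image; patches are flattened column-major to L = patch_edge**2.
    """
    if patch_edge > imset.edge:
        raise ValueError(
            f"patch_edge {patch_edge} exceeds image edge {imset.edge}"
        )
    rng = np.random.default_rng(seed)
    L = patch_edge * patch_edge
    out = np.empty((L, count))
    n_im = len(imset.images)
    hi = imset.edge - patch_edge + 1
    for j in range(count):
        im = imset.images[rng.integers(n_im)]
        r, c = rng.integers(hi), rng.integers(hi)
        out[:, j] = im[r : r + patch_edge, c : c + patch_edge].flatten(
            order=FLATTEN_ORDER
        )
    return out


def make_grating(spec: GratingSpec) -> np.ndarray:
    """Mean-zero sinusoidal grating patch flattened to a length-edge^2 vector."""
    theta = np.deg2rad(spec.orientation)
    phase = np.deg2rad(spec.phase)
    u = np.arange(spec.edge)[:, None]
    v = np.arange(spec.edge)[None, :]
    arg = (
        2.0
        * np.pi
        * spec.spatial_frequency
        * (u * np.cos(theta) + v * np.sin(theta))
        / spec.edge
        + phase
    )
    patch = spec.contrast * np.sin(arg)
    patch -= patch.mean()
    return patch.flatten(order=FLATTEN_ORDER)


def grating_sweep(
    edge: int,
    orientation: float,
    spatial_frequency: float,
    contrasts,
    phases,
    orientation_offset: float = 0.0,
) -> list[GratingSpec]:
    """Cartesian product of contrasts x phases at ``orientation + offset``."""
    return [
        GratingSpec(
            edge=edge,
            contrast=float(c),
            orientation=orientation + orientation_offset,
            spatial_frequency=spatial_frequency,
            phase=float(p),
        )
        for c in np.asarray(contrasts, dtype=float)
        for p in np.asarray(phases, dtype=float)
    ]
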