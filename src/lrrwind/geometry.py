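"""Solenoid geometry: core curve, parallel-transport framing, winding number.

The LRR solenoid coils around a central axis.  We recover that axis as a
Gaussian-smoothed copy of the Cα trace (the *core curve*), transport an
orthonormal frame of the core's normal plane along the curve with minimal
twist, project the backbone's displacement from the core onto that frame, and
accumulate the signed angle swept by the projected 2D curve around the
origin.  The resulting cumulative winding number w(s) increases by one per
coil turn on a solenoid and stays flat elsewhere — the signal every
downstream stage consumes.

Parallel transport uses the nearest-orthonormal-matrix (orthogonal
Procrustes) update: the previous frame is projected onto the next normal
plane and its singular values are replaced by ones.  The transported frame is
unique up to a global rotation/reflection of the plane, so |w| is invariant
to the random initial frame; we normalize orientation so w ends non-negative
and report the raw handedness separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import NumericalError
from .structure_io import BackboneCurve

NEAR_ORIGIN_GUARD = 1e-6  # Å; the winding integrand is singular at the origin


@dataclass(frozen=True)
class CoreCurve:
    """Gaussian-smoothed backbone — the estimated solenoid axis."""

    points: np.ndarray
    sigma_core: float


@dataclass(frozen=True)
class TangentField:
    """Unit tangent vectors of the core curve, one per residue."""

    vectors: np.ndarray
    sigma_deriv: float


@dataclass(frozen=True)
class FrameField:
    """Parallel-transported orthonormal pairs (u, v) spanning normal planes."""

    frames: np.ndarray  # (n, 2, 3); frames[i] rows are u_i, v_i
    seed: int


@dataclass(frozen=True)
class PlanarCurve:
    """2D projection of the backbone into the transported normal frame."""

    xy: np.ndarray  # (n, 2)


@dataclass(frozen=True)
class WindingProfile:
    """Cumulative winding number per residue; w[0] = 0, w[-1] >= 0.

    ``handedness`` is +1 if the raw profile already ended non-negative and
    -1 if it was negated during orientation normalization (i.e. the coil
    winds the other way relative to the random initial frame).
    """

    w: np.ndarray
    source_kind: str = "normal_bundle"
    handedness: int = 1

    def __len__(self) -> int:
        return len(self.w)


def gaussian_derivative_kernel(sigma: float, radius: Optional[int] = None) -> np.ndarray:
    """Discrete derivative-of-Gaussian kernel g'_sigma[j] for j in [-radius, radius].

    Values follow g'_sigma[j] = -j/(2*pi*sigma^3) * exp(-j^2 / (2*sigma^2));
    the kernel is antisymmetric and vanishes at j = 0.  ``radius`` defaults to
    ceil(4*sigma) and may not be smaller.

    Note the absolute scale of this kernel is immaterial wherever the result
    is normalized (tangent fields); where a true derivative is needed the
    caller rescales to unit response on a linear ramp (see
    :func:`derivative_filter`).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r_min = math.ceil(4 * sigma)
    if radius is None:
        radius = r_min
    if radius < r_min:
        raise ValueError(f"radius must be at least ceil(4*sigma) = {r_min}")
    j = np.arange(-radius, radius + 1, dtype=float)
    return -j / (2.0 * np.pi * sigma**3) * np.exp(-(j**2) / (2.0 * sigma**2))


def derivative_filter(signal: np.ndarray, sigma: float) -> np.ndarray:
    """Differentiate a sampled signal by Gaussian-derivative convolution.

    Reflect boundary handling; the discrete kernel is rescaled so that a
    linear ramp t -> a*t maps exactly to the constant a (unit DC-derivative
    response).  Works on 1D signals or column-stacked components (axis 0).
    """
    g = gaussian_derivative_kernel(sigma)
    radius = (len(g) - 1) // 2
    j = np.arange(-radius, radius + 1, dtype=float)
    scale = -float(np.sum(j * g))  # response of gamma * g' on the unit ramp
    weights = -g / scale  # correlate with g'[-j] == convolve with g'[j]
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        return ndimage.correlate1d(signal, weights, mode="reflect")
    return np.column_stack(
        [ndimage.correlate1d(signal[:, c], weights, mode="reflect")
         for c in range(signal.shape[1])]
    )


def smooth_core(backbone: BackboneCurve | np.ndarray, sigma_core: float) -> CoreCurve:
    """Estimate the solenoid axis by Gaussian-smoothing the backbone curve.

    Each coordinate component is convolved with a normalized Gaussian of
    bandwidth ``sigma_core`` residues (reflect boundaries, kernel radius
    ceil(4*sigma)).
    """
    if sigma_core <= 0:
        raise ValueError("sigma_core must be positive")
    pts = backbone.points if hasattr(backbone, "points") else np.asarray(backbone, float)
    radius = max(1, math.ceil(4 * sigma_core))
    smoothed = ndimage.gaussian_filter1d(
        pts, sigma_core, axis=0, mode="reflect", radius=radius
    )
    return CoreCurve(points=smoothed, sigma_core=float(sigma_core))


def tangent_field(core: CoreCurve | np.ndarray, sigma_deriv: float = 1.0) -> TangentField:
    """Unit tangents of a 3D curve via Gaussian-derivative convolution (sigma = 1
    by default), normalized per position."""
    pts = core.points if hasattr(core, "points") else np.asarray(core, float)
    radius = math.ceil(4 * sigma_deriv)
    if len(pts) < 2 * radius + 1:
        raise ValueError(
            f"curve of length {len(pts)} shorter than kernel support {2 * radius + 1}"
        )
    deriv = derivative_filter(pts, sigma_deriv)
    norms = np.linalg.norm(deriv, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if bad.size:
        raise NumericalError(
            f"zero-magnitude curve derivative at position {bad[0]} (stationary curve)"
        )
    return TangentField(vectors=deriv / norms[:, None], sigma_deriv=float(sigma_deriv))


def local_periodicity_power(
    points: np.ndarray, period: float, sigma_deriv: float = 1.0
) -> np.ndarray:
    """Windowed Fourier power of the backbone tangent field at the repeat
    frequency.

    The tangent vectors of a solenoid oscillate with one cycle per repeat
    period; outside the coil they do not.  For each residue the power of the
    period-``period`` Fourier component of the unit tangent field over a
    centered one-period window is returned (normalized so a pure sinusoid of
    unit amplitude gives ~0.25 per component).  This is a frame-independent
    boundary signal: it drops from its coil plateau to background across
    roughly half a window, crossing ~50% of the plateau at the coil edge.
    Edge positions where no full window fits take the nearest interior value.
    """
    pts = points.points if hasattr(points, "points") else np.asarray(points, float)
    tangents = tangent_field(pts, sigma_deriv).vectors
    n = len(tangents)
    window = int(round(period))
    if window < 3 or n < window + 1:
        return np.full(n, np.nan)
    phase = np.exp(-2j * np.pi * np.arange(n) / period)
    signal = tangents * phase[:, None]
    csum = np.vstack([np.zeros((1, 3), complex), np.cumsum(signal, axis=0)])
    starts = np.arange(n - window + 1)
    windowed = csum[starts + window] - csum[starts]
    power = np.sum(np.abs(windowed) ** 2, axis=1) / window**2
    out = np.full(n, np.nan)
    half = window // 2
    out[half : half + len(power)] = power
    out[:half] = power[0]
    out[half + len(power):] = power[-1]
    return out


def _random_normal_pair(tangent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random orthonormal pair spanning the plane perpendicular to ``tangent``."""
    for _ in range(64):
        a = rng.normal(size=3)
        u = a - np.dot(a, tangent) * tangent
        nu = np.linalg.norm(u)
        if nu > 1e-8:
            u /= nu
            break
    else:  # pragma: no cover - probability zero
        raise NumericalError("could not draw an initial normal vector")
    for _ in range(64):
        b = rng.normal(size=3)
        v = b - np.dot(b, tangent) * tangent - np.dot(b, u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            return np.vstack([u, v / nv])
    raise NumericalError("could not draw an initial normal frame")  # pragma: no cover


def parallel_transport_frames(tangents: TangentField, seed: int = 0) -> FrameField:
    """Transport a random initial normal frame along the curve with minimal twist.

    Frame 0 is a seeded random orthonormal pair perpendicular to tangent 0.
    Each subsequent frame is the previous one projected onto the next normal
    plane and snapped back to orthonormality by replacing the singular values
    of the projected 2x3 frame matrix with ones (orthogonal Procrustes).
    """
    t = tangents.vectors
    n = len(t)
    rng = np.random.default_rng(seed)
    frames = np.empty((n, 2, 3))
    frames[0] = _random_normal_pair(t[0], rng)
    for i in range(1, n):
        ti = t[i]
        projected = frames[i - 1] - np.outer(frames[i - 1] @ ti, ti)
        u_svd, s, vt = np.linalg.svd(projected, full_matrices=False)
        if s[-1] < 1e-8:
            raise NumericalError(
                f"rank-deficient frame projection at position {i} "
                "(consecutive tangents nearly antiparallel)"
            )
        frames[i] = u_svd @ vt
    return FrameField(frames=frames, seed=int(seed))


def project_normal_bundle(
    backbone: BackboneCurve | np.ndarray,
    core: CoreCurve,
    frames: FrameField,
) -> PlanarCurve:
    """Project backbone-minus-core displacements onto the transported frames."""
    pts = backbone.points if hasattr(backbone, "points") else np.asarray(backbone, float)
    if not (len(pts) == len(core.points) == len(frames.frames)):
        raise ValueError("backbone, core and frames must have equal length")
    d = pts - core.points
    x = np.einsum("ij,ij->i", d, frames.frames[:, 0, :])
    y = np.einsum("ij,ij->i", d, frames.frames[:, 1, :])
    return PlanarCurve(xy=np.column_stack([x, y]))


def winding_number(
    planar: PlanarCurve | np.ndarray,
    sigma_deriv: float = 1.0,
    source_kind: str = "normal_bundle",
) -> WindingProfile:
    """Cumulative winding number of a planar curve around the origin.

    Discretizes w(s) = (1/2pi) ∫ (x y' - y x') / (x² + y²) dt with
    Gaussian-derivative velocities and a cumulative sum; w[0] = 0.  The
    positions x, y entering the integrand are smoothed with the matching
    Gaussian so the summand is exactly dtheta/dt of the sigma-mollified
    curve; using raw positions against mollified velocities would bias every
    turn low by the kernel's frequency attenuation.  The profile is negated
    if it ends negative (orientation normalization), with the original
    handedness recorded on the result.
    """
    xy = planar.xy if hasattr(planar, "xy") else np.asarray(planar, float)
    bad = np.nonzero(np.linalg.norm(xy, axis=1) < NEAR_ORIGIN_GUARD)[0]
    if bad.size:
        raise NumericalError(
            f"projected point at residue index {bad[0]} lies within "
            f"{NEAR_ORIGIN_GUARD} of the origin; winding is ill-defined there"
        )
    radius = math.ceil(4 * sigma_deriv)
    xy_s = ndimage.gaussian_filter1d(xy, sigma_deriv, axis=0, mode="reflect",
                                     radius=radius)
    x, y = xy_s[:, 0], xy_s[:, 1]
    r2 = np.maximum(x * x + y * y, NEAR_ORIGIN_GUARD**2)
    xdot = derivative_filter(xy[:, 0], sigma_deriv)  # == d/dt of the smoothed x
    ydot = derivative_filter(xy[:, 1], sigma_deriv)
    integrand = (x * ydot - y * xdot) / (2.0 * np.pi * r2)
    c = np.cumsum(integrand)
    w = c - c[0]
    handedness = 1
    if w[-1] < 0:
        w = -w
        handedness = -1
    return WindingProfile(w=w, source_kind=source_kind, handedness=handedness)
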