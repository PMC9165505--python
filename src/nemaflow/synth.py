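"""Seeded synthetic-data generators with known ground truth.

These stand in for unreleased microscopy data: monolayers with a target
nematic order, nucleus/Golgi point sets with a target polarization bias,
Gaussian random velocity fields with a prescribed exponential correlation
length, and traction/displacement pairs with closed-form strain energy.
Every generator is a pure function of its spec (seed included).

Orientation angles use a von Mises distribution on the doubled angle
(nematic symmetry): the concentration kappa is solved so that
E[cos 2theta] = A1(kappa) = I1(kappa)/I0(kappa) matches the requested
target, which makes the mapping to the order parameter
S = E[cos^2 theta] - 1/3 monotone and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Voronoi
from scipy.special import i0, i1
from shapely.geometry import Polygon, box

from .flowfield import VectorField2D
from .monolayer import CellOutline
from .pcp import PointSet

__all__ = [
    "MonolayerSpec",
    "PCPSpec",
    "FieldSpec",
    "make_monolayer",
    "make_pcp_points",
    "make_correlated_field",
    "make_traction_pair",
    "vonmises_kappa_for_mean_cos",
]

_KAPPA_MAX = 500.0  # beyond this the wrapped distribution is effectively a delta


def vonmises_kappa_for_mean_cos(target: float) -> float:
    """Concentration kappa with A1(kappa) = I1/I0 = target, target in [0, 1)."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("target mean cosine must lie in [0, 1]")
    if target < 1e-12:
        return 0.0
    a1 = lambda k: i1(k) / i0(k)
    if target >= a1(_KAPPA_MAX):
        return _KAPPA_MAX
    return brentq(lambda k: a1(k) - target, 1e-9, _KAPPA_MAX, xtol=1e-12)


@dataclass(frozen=True)
class MonolayerSpec:
    """Synthetic monolayer: Voronoi cells stretched along sampled angles."""

    n_cells: int = 400
    target_order: float = 0.3  # S* = E[cos^2 theta] - 1/3, in [0, 2/3]
    mean_aspect_ratio: float = 4.0
    reference_direction: float = 0.0  # degrees
    field_size: float = 600.0  # um
    jitter: float = 0.15  # lattice jitter, fraction of spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.target_order <= 2.0 / 3.0:
            raise ValueError("target_order must lie in [0, 2/3]")
        if self.mean_aspect_ratio < 1.0:
            raise ValueError("mean_aspect_ratio must be >= 1")


@dataclass(frozen=True)
class PCPSpec:
    """Synthetic nucleus/Golgi detections with a target mean PCP index."""

    n_cells: int = 400
    polarization_bias: float = -0.5  # target E[cos phi], in [-1, 1]
    golgi_fragments_per_cell: int = 3
    displacement_um: float = 6.0
    fragment_scatter_um: float = 0.8
    angular_noise_kappa: float | None = None  # overrides the calibrated kappa
    spacing_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.polarization_bias) > 1.0:
            raise ValueError("polarization_bias must lie in [-1, 1]")
        if self.golgi_fragments_per_cell < 1:
            raise ValueError("need at least one golgi fragment per cell")


@dataclass(frozen=True)
class FieldSpec:
    """Gaussian random vector field with exponential spatial correlation."""

    grid_n: int = 256
    dx: float = 1.5  # um
    correlation_length: float = 20.0  # um
    rms: float = 10.0  # um/h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_n < 32:
            raise ValueError("grid_n must be >= 32")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.correlation_length < 2.0 * self.dx:
            raise ValueError(
                "correlation_length below 2*dx is unresolvable on the grid"
            )


def _sample_nematic_angles(rng, n: int, target_order: float) -> np.ndarray:
    """Angles theta (radians, about 0) with E[cos^2 theta] - 1/3 = S*."""
    mean_cos2t = 2.0 * target_order - 1.0 / 3.0  # E[cos 2theta]
    if mean_cos2t >= 0:
        kappa = vonmises_kappa_for_mean_cos(mean_cos2t)
        center = 0.0
    else:
        # concentrate about 90 deg instead: E[cos 2theta] < 0
        kappa = vonmises_kappa_for_mean_cos(-mean_cos2t)
        center = np.pi
    if kappa >= _KAPPA_MAX:
        two_theta = np.full(n, center)
    elif kappa == 0.0:
        two_theta = rng.uniform(-np.pi, np.pi, size=n) + center
    else:
        two_theta = rng.vonmises(center, kappa, size=n)
    return two_theta / 2.0


def _jittered_lattice(rng, n: int, extent: float, jitter_frac: float):
    """~n points on a jittered square lattice covering [0, extent]^2."""
    side = int(np.ceil(np.sqrt(n)))
    spacing = extent / side
    ix, iy = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack(
        [(ix.ravel() + 0.5) * spacing, (iy.ravel() + 0.5) * spacing]
    )
    pts += rng.normal(scale=jitter_frac * spacing, size=pts.shape)
    return pts, spacing


def _bounded_voronoi_polygons(points: np.ndarray, extent: float):
    """Voronoi polygons of ``points`` clipped to [0, extent]^2.

    The tessellation is bounded by mirroring all points across the four
    rectangle edges, so every interior cell is finite.
    """
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, extent), (1, 0.0), (1, extent)):
        m = points.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    rect = box(0.0, 0.0, extent, extent)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            polys.append(None)
            continue
        poly = Polygon(vor.vertices[region])
        poly = poly.intersection(rect)
        polys.append(poly if poly.geom_type == "Polygon" and poly.area > 0 else None)
    return polys


def _stretch_polygon(coords: np.ndarray, center: np.ndarray, theta: float, s: float):
    """Area-preserving stretch by s along theta and 1/s across, about center."""
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, sn], [-sn, c]])  # world -> stretch frame
    local = (coords - center) @ rot.T
    local[:, 0] *= s
    local[:, 1] /= s
    return local @ rot + center


def make_monolayer(spec: MonolayerSpec):
    """Synthetic segmented monolayer with a controlled orientation order.

    Returns ``(outlines, truth)`` where ``truth`` records the sampled
    per-cell angles (degrees, relative to the reference direction) and the
    target order. The ground-truth order of the *sample* is
    ``truth["sample_order"]``.
    """
    rng = np.random.default_rng(spec.seed)
    pts, _ = _jittered_lattice(rng, spec.n_cells, spec.field_size, spec.jitter)
    polys = _bounded_voronoi_polygons(pts, spec.field_size)
    theta = _sample_nematic_angles(rng, len(pts), spec.target_order)
    ref = np.radians(spec.reference_direction)
    stretch = np.sqrt(spec.mean_aspect_ratio)

    outlines = []
    angles_deg = []
    kept = 0
    for i, poly in enumerate(polys):
        if poly is None or kept >= spec.n_cells:
            continue
        coords = np.asarray(poly.exterior.coords)[:-1]
        world_angle = theta[i] + ref
        center = np.asarray(poly.centroid.coords[0])
        coords = _stretch_polygon(coords, center, world_angle, stretch)
        outlines.append(CellOutline(vertices=coords, cell_id=f"cell_{kept:04d}"))
        angles_deg.append(np.degrees(theta[i]))
        kept += 1

    angles = np.asarray(angles_deg)
    sample_order = float(np.mean(np.cos(np.radians(angles)) ** 2) - 1.0 / 3.0)
    truth = {
        "target_order": spec.target_order,
        "sample_order": sample_order,
        "angles_deg": angles.tolist(),
        "reference_direction": spec.reference_direction,
        "n_cells": len(outlines),
        "seed": spec.seed,
    }
    return outlines, truth


def make_pcp_points(spec: PCPSpec):
    """Synthetic nucleus/Golgi point sets with a target mean cos(phi).

    Flow is along +x. Returns ``(nuclei, golgi, truth)``; ``truth`` holds the
    per-cell polarity angles and the sample mean index.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.spacing_um * int(np.ceil(np.sqrt(spec.n_cells)))
    pts, spacing = _jittered_lattice(rng, spec.n_cells, extent, 0.1)
    pts = pts[: spec.n_cells]

    beta = spec.polarization_bias
    center = 0.0 if beta >= 0 else np.pi
    if spec.angular_noise_kappa is not None:
        kappa = spec.angular_noise_kappa
    else:
        kappa = vonmises_kappa_for_mean_cos(abs(beta))
    if abs(beta) >= 1.0 - 1e-12 or kappa >= _KAPPA_MAX:
        phi = np.full(len(pts), center)
        scatter = 0.0
    else:
        phi = rng.vonmises(center, kappa, size=len(pts)) if kappa > 0 else rng.uniform(
            -np.pi, np.pi, size=len(pts)
        )
        scatter = spec.fragment_scatter_um

    polarity = pts + spec.displacement_um * np.column_stack(
        [np.cos(phi), np.sin(phi)]
    )
    k = spec.golgi_fragments_per_cell
    frags = np.repeat(polarity, k, axis=0)
    if scatter > 0:
        frags = frags + rng.normal(scale=scatter, size=frags.shape)

    nuclei = PointSet(positions=pts, ids=np.arange(len(pts)), label="nucleus")
    golgi = PointSet(positions=frags, ids=np.arange(len(frags)), label="golgi")
    truth = {
        "polarization_bias": beta,
        "sample_mean_cos_phi": float(np.mean(np.cos(phi))),
        "phi_deg": np.degrees(phi).tolist(),
        "displacement_um": spec.displacement_um,
        "n_cells": len(pts),
        "seed": spec.seed,
    }
    return nuclei, golgi, truth


def _exponential_spectrum(k2: np.ndarray, lam: float) -> np.ndarray:
    """2D power spectrum of an isotropic exponential correlation exp(-r/lam)."""
    return (1.0 + k2 * lam**2) ** -1.5


def _correlated_scalar_field(rng, n: int, dx: float, lam: float) -> np.ndarray:
    kx = 2.0 * np.pi * np.fft.fftfreq(n, d=dx)
    k2 = kx[:, None] ** 2 + kx[None, :] ** 2
    amp = np.sqrt(_exponential_spectrum(k2, lam))
    noise = rng.normal(size=(n, n))
    f = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    return f - f.mean()


def make_correlated_field(spec: FieldSpec) -> VectorField2D:
    """Gaussian random velocity field with per-component correlation exp(-r/lam).

    Synthesised spectrally (periodic); the overall amplitude is rescaled so
    the empirical rms speed sqrt(mean(u^2 + v^2)) equals ``spec.rms``.
    """
    rng = np.random.default_rng(spec.seed)
    u = _correlated_scalar_field(rng, spec.grid_n, spec.dx, spec.correlation_length)
    v = _correlated_scalar_field(rng, spec.grid_n, spec.dx, spec.correlation_length)
    scale = spec.rms / np.sqrt(np.mean(u**2 + v**2))
    return VectorField2D(u=u * scale, v=v * scale, dx=spec.dx, kind="velocity")


def make_traction_pair(
    grid_n: int = 64,
    dx: float = 4.0,
    amplitude: float = 100.0,
    seed: int = 0,
    compliance: float = 0.02,
    correlation_length: float | None = None,
):
    """Traction/displacement pair with closed-form strain energy.

    The displacement is proportional to the traction, ``u = compliance * T``
    (um per Pa), so the Butler strain energy has the closed form
    ``U = (1/2) * compliance * sum |T|^2 * dx^2`` (converted to joules).
    Returns ``(traction, displacement, U_true_joules)``.
    """
    lam = correlation_length if correlation_length is not None else 8.0 * dx
    rng = np.random.default_rng(seed)
    tu = _correlated_scalar_field(rng, grid_n, dx, lam)
    tv = _correlated_scalar_field(rng, grid_n, dx, lam)
    if amplitude == 0:
        tu = np.zeros_like(tu)
        tv = np.zeros_like(tv)
    else:
        scale = amplitude / np.sqrt(np.mean(tu**2 + tv**2))
        tu *= scale
        tv *= scale
    traction = VectorField2D(u=tu, v=tv, dx=dx, kind="traction")
    displacement = VectorField2D(
        u=compliance * tu, v=compliance * tv, dx=dx, kind="displacement"
    )
    u_true = 0.5 * compliance * float(np.sum(tu**2 + tv**2)) * dx**2 * 1e-18
    return traction, displacement, u_true
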