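"""Velocity-field statistics and substrate strain energy.

Velocity fields live on a regular grid with spacing ``dx`` (um); speeds are
in um/h, tractions in Pa, displacements in um. The spatial velocity
autocorrelation C_vv(r) is isotropically binned over node pairs and fitted
with exp(-r / C_L) to extract the correlation length. The strain energy is
the Butler-type surface integral U = (1/2) sum (T . u) dx^2, converted to
joules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VectorField2D",
    "CorrelationFitError",
    "magnitude",
    "subtract_drift",
    "velocity_correlation",
    "correlation_length",
    "classify_stationary",
    "strain_energy",
    "save_field",
    "load_field",
    "MIGRATION_SPEED_THRESHOLD",
]

#: lower detection limit for actual migration (um/h); below it a cell is
#: considered stationary
MIGRATION_SPEED_THRESHOLD = 10.0

# Pa * um * um^2 -> J
_PA_UM3_TO_J = 1e-18


class CorrelationFitError(RuntimeError):
    """Raised when C_vv does not decay and no correlation length exists."""


@dataclass
class VectorField2D:
    """Gridded planar vector data (velocity, traction or displacement)."""

    u: np.ndarray
    v: np.ndarray
    dx: float
    kind: str = "velocity"

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2D arrays of identical shape")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


def magnitude(field: VectorField2D) -> np.ndarray:
    """Per-node speed M = sqrt(u^2 + v^2); NaN nodes propagate."""
    return np.hypot(field.u, field.v)


def subtract_drift(field: VectorField2D) -> VectorField2D:
    """Remove the mean velocity so that residual component means are zero."""
    if np.all(np.isnan(field.u)) or np.all(np.isnan(field.v)):
        raise ValueError("cannot subtract drift from an all-NaN field")
    return VectorField2D(
        u=field.u - np.nanmean(field.u),
        v=field.v - np.nanmean(field.v),
        dx=field.dx,
        kind=field.kind,
    )


def _autocorr_maps(field: VectorField2D, method: str):
    """Per-lag sums of delta-v dot products and valid pair counts.

    Returns arrays indexed by integer lag (dy, dx) over the zero-padded lag
    grid. ``method`` is "fft" (zero-padded FFT autocorrelation) or "direct"
    (O(N^2) sum, used as a test oracle).
    """
    ny, nx = field.shape
    mask = np.isfinite(field.u) & np.isfinite(field.v)
    u = np.where(mask, field.u, 0.0)
    v = np.where(mask, field.v, 0.0)
    if method == "fft":
        py, px = 2 * ny, 2 * nx
        fu = np.fft.rfft2(u, s=(py, px))
        fv = np.fft.rfft2(v, s=(py, px))
        fm = np.fft.rfft2(mask.astype(float), s=(py, px))
        num = np.fft.irfft2(np.abs(fu) ** 2 + np.abs(fv) ** 2, s=(py, px))
        cnt = np.fft.irfft2(np.abs(fm) ** 2, s=(py, px))
        # lags -(n-1) .. n-1 via fftshift-style reindexing
        num = np.roll(num, (ny - 1, nx - 1), axis=(0, 1))[: 2 * ny - 1, : 2 * nx - 1]
        cnt = np.roll(cnt, (ny - 1, nx - 1), axis=(0, 1))[: 2 * ny - 1, : 2 * nx - 1]
        cnt = np.round(cnt)
        return num, cnt
    if method == "direct":
        num = np.zeros((2 * ny - 1, 2 * nx - 1))
        cnt = np.zeros_like(num)
        for iy in range(ny):
            for ix in range(nx):
                if not mask[iy, ix]:
                    continue
                for jy in range(ny):
                    for jx in range(nx):
                        if not mask[jy, jx]:
                            continue
                        num[jy - iy + ny - 1, jx - ix + nx - 1] += (
                            u[iy, ix] * u[jy, jx] + v[iy, ix] * v[jy, jx]
                        )
                        cnt[jy - iy + ny - 1, jx - ix + nx - 1] += 1
        return num, cnt
    raise ValueError(f"unknown method {method!r}")


def velocity_correlation(
    field: VectorField2D,
    max_r: float | None = None,
    bin_width: float | None = None,
    method: str = "fft",
):
    """Isotropically binned spatial velocity correlation.

    C_vv(r) = <dv(x) . dv(x + r)> / <|dv|^2> with pairs binned by separation
    distance; the zero-separation bin is 1 by construction. The field should
    be drift-subtracted first. Returns (r_centers, C_vv).
    """
    ny, nx = field.shape
    mask = np.isfinite(field.u) & np.isfinite(field.v)
    if mask.sum() < 2:
        raise ValueError("need at least two finite nodes")
    if bin_width is None:
        bin_width = field.dx
    if max_r is None:
        max_r = min(ny, nx) // 2 * field.dx

    num, cnt = _autocorr_maps(field, method)
    dy = (np.arange(2 * ny - 1) - (ny - 1))[:, None] * field.dx
    dxs = (np.arange(2 * nx - 1) - (nx - 1))[None, :] * field.dx
    r = np.hypot(dy, dxs)

    sel = (cnt > 0) & (r <= max_r + 0.5 * bin_width)
    bin_idx = np.round(r[sel] / bin_width).astype(int)
    nbins = bin_idx.max() + 1
    num_b = np.bincount(bin_idx, weights=num[sel], minlength=nbins)
    cnt_b = np.bincount(bin_idx, weights=cnt[sel], minlength=nbins)
    valid = cnt_b > 0
    r_centers = np.arange(nbins)[valid] * bin_width
    corr = num_b[valid] / cnt_b[valid]
    return r_centers, corr / corr[0]


def correlation_length(r, c_vv, exclude_zero: bool = True):
    """Correlation length from a least-squares fit of exp(-r / C_L).

    Returns ``(C_L, residual)`` where residual is the RMS misfit. Raises
    :class:`CorrelationFitError` when the curve does not decay (the fitted
    length runs away or the optimiser fails).
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(c_vv, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 bins to fit")
    if exclude_zero:
        keep = r > 0
        r, c = r[keep], c[keep]
    r_scale = r.max()
    try:
        popt, _ = curve_fit(
            lambda x, cl: np.exp(-x / cl),
            r,
            c,
            p0=[max(r_scale / 5.0, r.min())],
            bounds=(1e-12, 1e9 * r_scale),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise CorrelationFitError(f"exponential fit failed: {exc}") from exc
    cl = float(popt[0])
    if cl > 100.0 * r_scale:
        raise CorrelationFitError(
            f"C_vv does not decay over the sampled range (fitted C_L = {cl:.3g})"
        )
    residual = float(np.sqrt(np.mean((np.exp(-r / cl) - c) ** 2)))
    return cl, residual


def classify_stationary(speeds) -> np.ndarray:
    """Boolean mask: True where speed < 10 um/h (stationary cells)."""
    s = np.asarray(speeds, dtype=float)
    return s < MIGRATION_SPEED_THRESHOLD


def strain_energy(
    traction: VectorField2D,
    displacement: VectorField2D,
    half_factor: bool = True,
) -> float:
    """Total strain energy in joules.

    U = (1/2) sum (T . u) dx^2 with T in Pa, u in um and dx in um. The 1/2
    prefactor follows the cited elastic-work formulation; set
    ``half_factor=False`` for the bare surface integral.
    """
    if traction.shape != displacement.shape:
        raise ValueError("traction and displacement grids must match")
    dot = traction.u * displacement.u + traction.v * displacement.v
    total = np.nansum(dot) * traction.dx**2 * _PA_UM3_TO_J
    return float(0.5 * total if half_factor else total)


def save_field(path, field: VectorField2D) -> None:
    np.savez(path, u=field.u, v=field.v, dx_um=field.dx, kind=field.kind)


def load_field(path) -> VectorField2D:
    with np.load(path, allow_pickle=False) as npz:
        return VectorField2D(
            u=npz["u"],
            v=npz["v"],
            dx=float(npz["dx_um"]),
            kind=str(npz["kind"]) if "kind" in npz else "velocity",
        )
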