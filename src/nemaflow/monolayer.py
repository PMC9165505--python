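"""Shape and orientation metrics for segmented monolayer cells.

Each cell outline (a simple planar polygon, coordinates in micrometres) is
summarised by its moment-equivalent ellipse: the ellipse sharing the
polygon's centroid, second central area moments (hence axis directions and
axis ratio) and area. Orientation angles are measured counterclockwise from
a reference direction and folded to [0, 90] degrees; the experimental
nematic order parameter is S = <cos^2 theta> - 1/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellOutline",
    "EllipseFit",
    "fit_ellipse",
    "aspect_ratio",
    "orientation_angle",
    "fold_angle",
    "order_parameter",
    "orientation_summary",
    "analyze_outlines",
    "outlines_from_geojson",
    "outlines_from_csv",
    "outlines_to_geojson",
]


@dataclass(frozen=True)
class CellOutline:
    """Ordered polygon vertices (um) with a cell identifier."""

    vertices: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (n >= 3, 2) array")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a polygon.

    ``angle`` is the major-axis direction in degrees, in [0, 180).
    ``degenerate`` flags (near-)circular fits whose angle is meaningless.
    """

    centroid: tuple[float, float]
    major_semiaxis: float
    minor_semiaxis: float
    angle: float
    degenerate: bool = False


def _polygon_moments(vertices: np.ndarray):
    """Signed area, centroid and second central moments via Green's theorem."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        raise ValueError("degenerate polygon: zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    # raw second moments about the origin
    ixx = ((x**2 + x * xn + xn**2) * cross).sum() / 12.0
    iyy = ((y**2 + y * yn + yn**2) * cross).sum() / 12.0
    ixy = ((2 * x * y + x * yn + xn * y + 2 * xn * yn) * cross).sum() / 24.0
    a = abs(area)
    sgn = np.sign(area)
    # normalized central moments (covariance of the uniform area measure)
    mxx = sgn * ixx / a - cx**2
    myy = sgn * iyy / a - cy**2
    mxy = sgn * ixy / a - cx * cy
    return a, (cx, cy), np.array([[mxx, mxy], [mxy, myy]])


def fit_ellipse(outline: CellOutline, degenerate_tol: float = 1e-9) -> EllipseFit:
    """Equivalent ellipse from exact polygon area moments.

    Axis directions and the a/b ratio come from the eigen-decomposition of
    the second-central-moment matrix; the absolute scale is set so the
    ellipse area equals the polygon area.
    """
    area, centroid, cov = _polygon_moments(outline.vertices)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    if vals[0] <= 0:
        raise ValueError(f"degenerate polygon (cell {outline.cell_id!r})")
    a_m = 2.0 * np.sqrt(vals[1])
    b_m = 2.0 * np.sqrt(vals[0])
    # rescale to match the polygon area exactly
    k = np.sqrt(area / (np.pi * a_m * b_m))
    a_m *= k
    b_m *= k
    major = vecs[:, 1]
    angle = np.degrees(np.arctan2(major[1], major[0])) % 180.0
    rel_gap = (vals[1] - vals[0]) / (vals[1] + vals[0])
    return EllipseFit(
        centroid=centroid,
        major_semiaxis=float(a_m),
        minor_semiaxis=float(b_m),
        angle=float(angle),
        degenerate=bool(rel_gap < degenerate_tol),
    )


def aspect_ratio(fit: EllipseFit) -> float:
    """Major/minor axis ratio; 1 for a perfect circle, > 1 otherwise."""
    return fit.major_semiaxis / fit.minor_semiaxis


def fold_angle(angle_deg) -> np.ndarray | float:
    """Fold an orientation to the acute range [0, 90] degrees."""
    a = np.asarray(angle_deg, dtype=float) % 180.0
    out = np.where(a > 90.0, 180.0 - a, a)
    return out if out.ndim else float(out)


def orientation_angle(fit: EllipseFit, reference_deg: float = 0.0) -> float:
    """Acute angle between the fitted major axis and a reference direction.

    Returns NaN for degenerate (circular) fits, whose axis is undefined.
    """
    if fit.degenerate:
        return float("nan")
    return float(fold_angle(fit.angle - reference_deg))


def order_parameter(angles_deg: Sequence[float]) -> float:
    """Experimental nematic order parameter S = <cos^2 theta> - 1/3."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("order_parameter needs at least one angle")
    return float(np.mean(np.cos(np.radians(a)) ** 2) - 1.0 / 3.0)


def orientation_summary(angles_deg: Sequence[float]):
    """(mean, sd, n) of folded orientation angles; mean near 45 deg flags isotropy."""
    a = fold_angle(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("orientation_summary needs at least one angle")
    sd = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return float(np.mean(a)), sd, int(a.size)


def analyze_outlines(
    outlines: Sequence[CellOutline], reference_deg: float = 0.0
) -> tuple[pd.DataFrame, dict]:
    """Per-cell table and population summary for a set of outlines."""
    rows = []
    for cell in outlines:
        fit = fit_ellipse(cell)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "centroid_x": fit.centroid[0],
                "centroid_y": fit.centroid[1],
                "aspect_ratio": aspect_ratio(fit),
                "orientation_deg": orientation_angle(fit, reference_deg),
            }
        )
    df = pd.DataFrame(rows)
    angles = df["orientation_deg"].dropna().to_numpy()
    mean, sd, n = orientation_summary(angles)
    summary = {
        "n_cells": int(len(df)),
        "n_oriented": n,
        "mean_angle_deg": mean,
        "sd_angle_deg": sd,
        "order_parameter": order_parameter(angles),
        "mean_aspect_ratio": float(df["aspect_ratio"].mean()),
        "reference_deg": float(reference_deg),
    }
    return df, summary


# ---------------------------------------------------------------------------
# I/O


def outlines_from_geojson(path) -> list[CellOutline]:
    with open(path) as fh:
        gj = json.load(fh)
    cells = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"feature {i}: expected Polygon, got {geom.get('type')}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        cell_id = str(feat.get("properties", {}).get("cell_id", i))
        cells.append(CellOutline(vertices=ring, cell_id=cell_id))
    return cells


def outlines_from_csv(path) -> list[CellOutline]:
    """Long-format CSV with columns cell_id, vertex_index, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"cell_id", "vertex_index", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"outline CSV needs columns {sorted(required)}")
    cells = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        cells.append(
            CellOutline(vertices=grp[["x_um", "y_um"]].to_numpy(), cell_id=str(cid))
        )
    return cells


def outlines_to_geojson(outlines: Sequence[CellOutline], path) -> None:
    features = []
    for cell in outlines:
        ring = cell.vertices.tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"cell_id": cell.cell_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
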