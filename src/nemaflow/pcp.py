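"""Planar-cell-polarity quantification from nucleus and Golgi detections.

Golgi detections are associated to the nucleus whose Voronoi cell contains
them (equivalently: the nearest nucleus), multiple fragments are collapsed
to a distance-weighted position, and the nucleus-to-Golgi vector is compared
with the flow direction: phi is the angle between the two and the PCP index
is cos(phi). Under this convention Golgi displaced *against* the flow
(upstream polarity) gives an index of -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "PointSet",
    "PCPRecord",
    "voronoi_assign",
    "weighted_golgi_position",
    "pcp_index",
    "pcp_distribution",
    "analyze_pcp",
    "points_from_csv",
    "points_to_csv",
]

#: guard distance (um) added to the nucleus-Golgi distance in the weights
DEFAULT_WEIGHT_GUARD = 0.1


@dataclass
class PointSet:
    """Planar detections of one structure class.

    ``positions`` is an (n, 2) array in micrometres; ``ids`` are per-point
    identifiers (nuclei ids are used for the assignment tie rule: on an
    exact distance tie, the lowest id wins).
    """

    positions: np.ndarray
    ids: np.ndarray | None = None
    label: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if p.size and (p.ndim != 2 or p.shape[1] != 2):
            raise ValueError("positions must be an (n, 2) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("positions must be finite")
        self.positions = p.reshape(-1, 2)
        if self.ids is None:
            self.ids = np.arange(len(self.positions))
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.positions):
                raise ValueError("ids and positions length mismatch")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class PCPRecord:
    nucleus_id: object
    nucleus_pos: tuple[float, float]
    golgi_pos: tuple[float, float]
    phi: float  # angle vs flow, degrees in [0, 180]
    phi_signed: float  # full-circle vector angle vs flow, degrees in [0, 360)
    pcp_index: float  # cos(phi)


def voronoi_assign(nuclei: PointSet, golgi: PointSet) -> dict:
    """Map nucleus id -> list of golgi indices inside its Voronoi cell.

    Point-in-Voronoi-cell membership is exactly nearest-nucleus assignment;
    exact ties go to the lowest nucleus id. An empty golgi set yields a
    mapping of empty lists.
    """
    if len(nuclei) < 1:
        raise ValueError("need at least one nucleus")
    order = np.argsort(nuclei.ids, kind="stable")
    mapping: dict = {nid: [] for nid in nuclei.ids}
    if len(golgi) == 0:
        return mapping
    d = cdist(golgi.positions, nuclei.positions[order])
    nearest = np.argmin(d, axis=1)  # argmin returns first (= lowest id) on ties
    for g_idx, col in enumerate(nearest):
        mapping[nuclei.ids[order[col]]].append(g_idx)
    return mapping


def weighted_golgi_position(
    nucleus_pos,
    golgi_positions,
    guard: float = DEFAULT_WEIGHT_GUARD,
) -> np.ndarray:
    """Distance-weighted mean Golgi position, weights w_i = 1/(d_i + guard)."""
    g = np.atleast_2d(np.asarray(golgi_positions, dtype=float))
    if g.shape[0] < 1:
        raise ValueError("need at least one golgi position")
    n = np.asarray(nucleus_pos, dtype=float)
    d = np.linalg.norm(g - n, axis=1)
    w = 1.0 / (d + guard)
    return (w[:, None] * g).sum(axis=0) / w.sum()


def pcp_index(nucleus_pos, golgi_pos, flow_direction) -> PCPRecord:
    """PCP record for one nucleus: angle vs flow and its cosine.

    ``flow_direction`` is any non-zero vector; coincident nucleus/Golgi
    positions have no direction and raise ValueError.
    """
    n = np.asarray(nucleus_pos, dtype=float)
    g = np.asarray(golgi_pos, dtype=float)
    v = g - n
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("nucleus and golgi positions coincide: PCP undefined")
    f = np.asarray(flow_direction, dtype=float)
    f = f / np.linalg.norm(f)
    cosphi = float(np.clip(np.dot(v, f) / norm, -1.0, 1.0))
    phi = float(np.degrees(np.arccos(cosphi)))
    # signed full-circle angle of v measured CCW from the flow direction
    cross = float(f[0] * v[1] - f[1] * v[0])
    phi_signed = float(np.degrees(np.arctan2(cross, np.dot(v, f))) % 360.0)
    return PCPRecord(
        nucleus_id=None,
        nucleus_pos=(n[0], n[1]),
        golgi_pos=(g[0], g[1]),
        phi=phi,
        phi_signed=phi_signed,
        pcp_index=cosphi,
    )


def pcp_distribution(records: Sequence[PCPRecord], bins: int = 12):
    """Normalized angular histogram of signed vector angles over [0, 360).

    Returns (bin_edges_deg, counts); counts sum to the number of records.
    """
    if len(records) == 0:
        raise ValueError("need at least one PCP record")
    angles = np.array([r.phi_signed for r in records])
    counts, edges = np.histogram(angles, bins=bins, range=(0.0, 360.0))
    return edges, counts


def analyze_pcp(
    nuclei: PointSet,
    golgi: PointSet,
    flow_deg: float = 0.0,
    guard: float = DEFAULT_WEIGHT_GUARD,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: assignment, weighting, per-nucleus records, summary.

    Nuclei without any assigned Golgi are dropped from the index statistics
    and counted in the summary.
    """
    flow = np.array([np.cos(np.radians(flow_deg)), np.sin(np.radians(flow_deg))])
    mapping = voronoi_assign(nuclei, golgi)
    id_to_pos = dict(zip(nuclei.ids.tolist(), nuclei.positions))
    rows = []
    dropped = 0
    for nid, g_idx in mapping.items():
        if not g_idx:
            dropped += 1
            continue
        npos = id_to_pos[nid]
        gpos = weighted_golgi_position(npos, golgi.positions[g_idx], guard=guard)
        if np.allclose(gpos, npos):
            dropped += 1
            continue
        rec = pcp_index(npos, gpos, flow)
        rows.append(
            {
                "nucleus_id": nid,
                "nucleus_x": npos[0],
                "nucleus_y": npos[1],
                "golgi_x": gpos[0],
                "golgi_y": gpos[1],
                "n_fragments": len(g_idx),
                "phi_deg": rec.phi,
                "phi_signed_deg": rec.phi_signed,
                "pcp_index": rec.pcp_index,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_nuclei": int(len(nuclei)),
        "n_scored": int(len(df)),
        "n_dropped": int(dropped),
        "mean_pcp_index": float(df["pcp_index"].mean()) if len(df) else float("nan"),
        "flow_deg": float(flow_deg),
    }
    return df, summary


def points_from_csv(path) -> tuple[PointSet, PointSet]:
    """Read detections CSV (frame, label in {nucleus, golgi}, id, x_um, y_um)."""
    df = pd.read_csv(path)
    required = {"label", "id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"points CSV needs columns {sorted(required)}")
    sets = {}
    for label in ("nucleus", "golgi"):
        sub = df[df["label"] == label]
        sets[label] = PointSet(
            positions=sub[["x_um", "y_um"]].to_numpy(),
            ids=sub["id"].to_numpy(),
            label=label,
        )
    return sets["nucleus"], sets["golgi"]


def points_to_csv(nuclei: PointSet, golgi: PointSet, path) -> None:
    frames = []
    for ps, label in ((nuclei, "nucleus"), (golgi, "golgi")):
        frames.append(
            pd.DataFrame(
                {
                    "frame": ps.frame,
                    "label": label,
                    "id": ps.ids,
                    "x_um": ps.positions[:, 0],
                    "y_um": ps.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
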