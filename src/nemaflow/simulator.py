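"""Landau-de Gennes Q-tensor relaxation on a 2D lattice.

Each lattice site carries a 3x3 symmetric traceless order tensor Q and a
Landau cubic sign ``b_site`` in {-1, +1}: rod-like elements (b = -1) order
into prolate uniaxial states, disk-like ("senescent") elements (b = +1)
prefer oblate states and do not align under the field.

The free energy per site is

    f = (A/2) tr Q^2 + (B/3) tr Q^3 + (C/4) (tr Q^2)^2
        + (R1/2) sum_k |d_k Q|^2  -  (delta_eps(omega)/2) E^T Q E

and the dynamics are the over-damped gradient flow dQ/dt = Gamma * H with H
the symmetric-traceless molecular field, integrated with forward Euler. The
frequency omega enters only through the anisotropy delta_eps(omega); the
field amplitude E is constant.

Directors are initialised in-plane; the dynamics close on the subspace with
Q_xz = Q_yz = 0, so the negative-anisotropy state aligns along y. A small
seeded perturbation is injected at every frequency switch (``switch_jitter``)
to break the residual y/z degeneracy of fully relaxed states, standing in
for thermal fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dielectric import DielectricParams, delta_eps, zero_crossing

__all__ = [
    "SimulationConfig",
    "QTensorField",
    "SimulationTrace",
    "SimulationDivergedError",
    "init_random",
    "free_energy",
    "bulk_energy_density",
    "step",
    "run_protocol",
    "protocol_schedule",
    "site_order",
    "mean_director_angle",
    "senescence_sweep",
    "PROTOCOLS",
]

_I3 = np.eye(3)

#: canned frequency-switch protocols: (omega label sequence, switch times)
PROTOCOLS = ("fig3a", "fig3b", "fig4a", "fig4b")


class SimulationDivergedError(RuntimeError):
    """Raised when a Q component exceeds the divergence guard."""


@dataclass(frozen=True)
class SimulationConfig:
    """Lattice, Landau coefficients, field and integration settings."""

    grid_nx: int = 64
    grid_ny: int = 64
    dx: float = 1.0
    A_coef: float = -0.05
    C_coef: float = 1.0
    B_rod: float = -1.0
    B_disk: float = 1.0
    R1: float = 1.0
    E_vec: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dt: float = 0.05
    Gamma: float = 1.0
    dielectric: DielectricParams = dc_field(default_factory=DielectricParams)
    seed: int = 0
    disk_fraction: float = 0.0
    coupling_mode: str = "full"
    boundary: str = "periodic"
    s_init: float = 0.05
    snapshot_interval: float = 1.0
    switch_jitter: float = 1e-3
    omega_low: float = 1.1
    omega_high: float = 6.3
    divergence_guard: float = 10.0

    def __post_init__(self) -> None:
        if self.C_coef <= 0:
            raise ValueError("C_coef must be positive (bounded free energy)")
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.disk_fraction <= 1.0:
            raise ValueError("disk_fraction must lie in [0, 1]")
        if self.coupling_mode not in ("full", "decoupled"):
            raise ValueError("coupling_mode must be 'full' or 'decoupled'")
        if self.boundary not in ("periodic", "neumann"):
            raise ValueError("boundary must be 'periodic' or 'neumann'")

    @property
    def omega_zero(self) -> float:
        return zero_crossing(self.dielectric)


@dataclass
class QTensorField:
    """Per-site order tensor state.

    Attributes
    ----------
    q : ndarray, shape (ny, nx, 3, 3)
        Symmetric traceless tensor at every site.
    b_site : ndarray, shape (ny, nx)
        Landau cubic sign, -1 (rod-like) or +1 (disk-like).
    time : float
        Current model time.
    """

    q: np.ndarray
    b_site: np.ndarray
    time: float = 0.0

    def copy(self) -> "QTensorField":
        return QTensorField(self.q.copy(), self.b_site.copy(), self.time)


@dataclass
class SimulationTrace:
    """Snapshot series recorded by :func:`run_protocol`."""

    times: np.ndarray
    mean_S: np.ndarray
    free_energy: np.ndarray
    director_angle: np.ndarray
    S_heatmaps: np.ndarray  # (n_snapshots, ny, nx)
    switch_times: tuple[float, ...]
    switch_indices: tuple[int, ...]  # snapshot index right after each switch
    final_field: QTensorField

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean_S": self.mean_S,
                "free_energy": self.free_energy,
                "director_angle_deg": self.director_angle,
            }
        )


def _uniaxial(s: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Uniaxial in-plane Q = s (n n^T - I/3), n = (cos theta, sin theta, 0)."""
    nx = np.cos(theta)
    ny = np.sin(theta)
    n = np.stack([nx, ny, np.zeros_like(theta)], axis=-1)
    nn = n[..., :, None] * n[..., None, :]
    return np.asarray(s)[..., None, None] * (nn - _I3 / 3.0)


def init_random(config: SimulationConfig) -> QTensorField:
    """Weakly nematic start: iid uniform in-plane directors at order s_init.

    Disk-like sites (b = +1) are assigned at exactly
    ``round(disk_fraction * N)`` positions drawn without replacement from the
    config seed; everything is deterministic given the config.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.grid_ny, config.grid_nx
    theta = rng.uniform(0.0, np.pi, size=(ny, nx))
    q = _uniaxial(np.full((ny, nx), config.s_init), theta)
    b = np.full((ny, nx), -1.0)
    n_disk = int(round(config.disk_fraction * ny * nx))
    if n_disk:
        idx = rng.choice(ny * nx, size=n_disk, replace=False)
        b.ravel()[idx] = 1.0
    return QTensorField(q=q, b_site=b, time=0.0)


def _neighbor_shifts(q: np.ndarray, axis: int, boundary: str):
    """Forward/backward neighbour arrays along a lattice axis."""
    fwd = np.roll(q, -1, axis=axis)
    bwd = np.roll(q, 1, axis=axis)
    if boundary == "neumann":
        if axis == 0:
            fwd[-1] = q[-1]
            bwd[0] = q[0]
        else:
            fwd[:, -1] = q[:, -1]
            bwd[:, 0] = q[:, 0]
    return fwd, bwd


def _bond_weights(b_site: np.ndarray, axis: int, boundary: str, mode: str):
    """Weights of forward/backward elastic bonds (0 cuts unlike species)."""
    if mode == "full":
        return 1.0, 1.0
    fwd = np.roll(b_site, -1, axis=axis)
    bwd = np.roll(b_site, 1, axis=axis)
    w_fwd = (b_site == fwd).astype(float)
    w_bwd = (b_site == bwd).astype(float)
    if boundary == "neumann":
        if axis == 0:
            w_fwd[-1] = 0.0
            w_bwd[0] = 0.0
        else:
            w_fwd[:, -1] = 0.0
            w_bwd[:, 0] = 0.0
    return w_fwd[..., None, None], w_bwd[..., None, None]


def bulk_energy_density(s: float, A: float, B: float, C: float) -> float:
    """Scalar bulk energy of a uniaxial state of order ``s``.

    Uses the trace identities tr Q^2 = 2 s^2 / 3 and tr Q^3 = 2 s^3 / 9.
    """
    return A * s**2 / 3.0 + 2.0 * B * s**3 / 27.0 + C * s**4 / 9.0


def free_energy(field: QTensorField, config: SimulationConfig, omega: float) -> float:
    """Total discrete free energy of the lattice at frequency ``omega``."""
    q = field.q
    b = field.b_site[..., None, None]
    trq2 = np.einsum("...ij,...ji->...", q, q)
    trq3 = np.einsum("...ij,...jk,...ki->...", q, q, q)
    bulk = (
        0.5 * config.A_coef * trq2
        + (field.b_site / 3.0) * trq3
        + 0.25 * config.C_coef * trq2**2
    )
    de = delta_eps(config.dielectric, omega)
    e = np.asarray(config.E_vec, dtype=float)
    eqe = np.einsum("i,...ij,j->...", e, q, e)
    cell = config.dx**2
    total = cell * float(np.sum(bulk - 0.5 * de * eqe))

    # elastic part: one term per bond, (R1/2) |Q_i - Q_j|^2 / dx^2 * dx^2
    _ = b  # b enters only through bond weights below
    for axis in (0, 1):
        fwd, _bwd = _neighbor_shifts(q, axis, config.boundary)
        w_fwd, _w = _bond_weights(field.b_site, axis, config.boundary, config.coupling_mode)
        diff = fwd - q
        if config.boundary == "neumann":
            # forward bond at the far edge duplicates nothing: diff is 0 there
            pass
        sq = np.einsum("...ij,...ij->...", diff, diff)
        if isinstance(w_fwd, np.ndarray):
            sq = sq * w_fwd[..., 0, 0]
        total += 0.5 * config.R1 * float(np.sum(sq))
    return total


def _molecular_field(
    field: QTensorField, config: SimulationConfig, de: float
) -> np.ndarray:
    """Symmetric-traceless molecular field H driving dQ/dt = Gamma H."""
    q = field.q
    b = field.b_site[..., None, None]
    trq2 = np.einsum("...ij,...ji->...", q, q)[..., None, None]
    q2 = q @ q
    h = -(config.A_coef * q + b * q2 + config.C_coef * q * trq2)

    e = np.asarray(config.E_vec, dtype=float)
    h = h + 0.5 * de * np.einsum("i,j->ij", e, e)

    lap = np.zeros_like(q)
    inv_dx2 = 1.0 / config.dx**2
    for axis in (0, 1):
        fwd, bwd = _neighbor_shifts(q, axis, config.boundary)
        w_fwd, w_bwd = _bond_weights(field.b_site, axis, config.boundary, config.coupling_mode)
        lap += (w_fwd * (fwd - q) + w_bwd * (bwd - q)) * inv_dx2
    h = h + config.R1 * lap

    # project onto symmetric traceless subspace
    h = 0.5 * (h + np.swapaxes(h, -1, -2))
    tr = np.einsum("...ii->...", h)[..., None, None]
    return h - tr * _I3 / 3.0


def step(field: QTensorField, config: SimulationConfig, omega: float) -> QTensorField:
    """One forward-Euler relaxation step at frequency ``omega``."""
    de = delta_eps(config.dielectric, omega)
    h = _molecular_field(field, config, de)
    q_new = field.q + config.dt * config.Gamma * h
    if np.max(np.abs(q_new)) > config.divergence_guard:
        raise SimulationDivergedError(
            f"Q diverged (component > {config.divergence_guard}); "
            f"reduce dt (currently dt={config.dt})"
        )
    return QTensorField(q=q_new, b_site=field.b_site, time=field.time + config.dt)


def site_order(field: QTensorField, degenerate_tol: float = 1e-9):
    """Per-site scalar order and director from eigen-decomposition.

    The scalar order is the signed uniaxial fit ``S = (3/2) * lambda_sel``
    where ``lambda_sel`` is the eigenvalue of largest magnitude, so prolate
    (rod-ordered) sites report S > 0 and oblate (disk-like) sites report
    S < 0, consistent with the round trip Q = S (n n^T - I/3) for either
    sign. The director is the eigenvector of the *largest* eigenvalue; sites
    whose top eigenvalues are degenerate (oblate states, Q = 0) carry NaN
    directors.
    """
    vals, vecs = np.linalg.eigh(field.q)
    lam_sel = np.where(np.abs(vals[..., 0]) > vals[..., 2], vals[..., 0], vals[..., 2])
    s = 1.5 * lam_sel
    n = vecs[..., :, 2]
    degenerate = (vals[..., 2] - vals[..., 1]) < degenerate_tol
    n = np.where(degenerate[..., None], np.nan, n)
    return s, n


def mean_director_angle(field: QTensorField) -> float:
    """In-plane angle (deg, folded to [0, 90]) of the lattice-mean Q director.

    NaN when the mean tensor has no unique leading in-plane axis.
    """
    q_mean = field.q.mean(axis=(0, 1))
    vals, vecs = np.linalg.eigh(q_mean)
    if vals[2] - vals[1] < 1e-9:
        return float("nan")
    n = vecs[:, 2]
    in_plane = np.hypot(n[0], n[1])
    if in_plane < 1e-6:
        return float("nan")
    ang = np.degrees(np.arctan2(abs(n[1]), abs(n[0])))
    return float(ang)


def protocol_schedule(name: str, config: SimulationConfig):
    """Frequency schedule [(omega, end_time), ...] for a canned protocol."""
    w0 = config.omega_zero
    wl, wh = config.omega_low, config.omega_high
    if name == "fig3a":
        return [(w0, 100.0), (wl, 250.0)]
    if name == "fig3b":
        return [(w0, 100.0), (wh, 250.0)]
    if name == "fig4a":
        return [(w0, 100.0), (wl, 250.0), (wh, 500.0)]
    if name == "fig4b":
        return [(w0, 100.0), (wh, 250.0), (wl, 500.0)]
    raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOLS}")


def _apply_switch_jitter(field: QTensorField, config: SimulationConfig, rng) -> None:
    """Seeded symmetry-breaking kick applied in place at a frequency switch."""
    if config.switch_jitter <= 0:
        return
    ny, nx = field.b_site.shape
    theta = rng.uniform(0.0, np.pi, size=(ny, nx))
    field.q += _uniaxial(np.full((ny, nx), config.switch_jitter), theta)


def run_protocol(
    config: SimulationConfig,
    schedule: Sequence[tuple[float, float]] | str,
    initial: QTensorField | None = None,
) -> SimulationTrace:
    """Run the gradient flow under a piecewise-constant frequency schedule.

    ``schedule`` is a list of ``(omega, end_time)`` pairs with strictly
    increasing end times, or the name of a canned protocol. Snapshots (mean
    order, free energy, director angle, per-site S map) are recorded every
    ``config.snapshot_interval`` time units and at segment boundaries.
    """
    if isinstance(schedule, str):
        schedule = protocol_schedule(schedule, config)
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must contain at least one (omega, end_time)")
    ends = [t for _, t in schedule]
    if any(b <= a for a, b in zip(ends, ends[1:])) or ends[0] <= 0:
        raise ValueError("schedule end times must be positive and strictly increasing")

    field = initial.copy() if initial is not None else init_random(config)
    jitter_rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**63))

    times, mean_s, energy, angle, heatmaps = [], [], [], [], []

    def record(omega: float) -> None:
        s, _ = site_order(field)
        times.append(field.time)
        mean_s.append(float(s.mean()))
        energy.append(free_energy(field, config, omega))
        angle.append(mean_director_angle(field))
        heatmaps.append(s.copy())

    switch_times = []
    switch_indices = []
    record(schedule[0][0])
    next_snap = config.snapshot_interval
    for seg, (omega, end_time) in enumerate(schedule):
        if seg > 0:
            switch_times.append(field.time)
            _apply_switch_jitter(field, config, jitter_rng)
            record(omega)  # state right after the switch, new omega
            switch_indices.append(len(times) - 1)
        n_steps = int(round((end_time - field.time) / config.dt))
        for _ in range(n_steps):
            field = step(field, config, omega)
            if field.time >= next_snap - 1e-9:
                record(omega)
                next_snap += config.snapshot_interval

    return SimulationTrace(
        times=np.asarray(times),
        mean_S=np.asarray(mean_s),
        free_energy=np.asarray(energy),
        director_angle=np.asarray(angle),
        S_heatmaps=np.asarray(heatmaps),
        switch_times=tuple(switch_times),
        switch_indices=tuple(switch_indices),
        final_field=field,
    )


def senescence_sweep(
    config: SimulationConfig,
    fractions: Iterable[float],
    omega: float,
    replicates: int = 3,
    equilibration_time: float = 100.0,
    field_time: float = 150.0,
    steady_window: float = 10.0,
) -> pd.DataFrame:
    """Steady-state mean order versus disk-like (senescent) fraction.

    For every fraction ``p`` the standard protocol (zero-anisotropy
    equilibration followed by the field phase at ``omega``) is run for
    ``replicates`` seeds; the steady S-bar is the time average of mean_S over
    the trailing ``steady_window`` time units. Returns a DataFrame with
    columns ``p``, ``mean_S``, ``sd_S``, ``n``.
    """
    fractions = list(fractions)
    if any(not 0.0 <= p <= 1.0 for p in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    w0 = config.omega_zero
    rows = []
    for p in fractions:
        vals = []
        for rep in range(replicates):
            cfg = replace(config, disk_fraction=p, seed=config.seed + 1000 * rep)
            trace = run_protocol(
                cfg,
                [(w0, equilibration_time), (omega, equilibration_time + field_time)],
            )
            tail = trace.times >= trace.times[-1] - steady_window
            vals.append(float(trace.mean_S[tail].mean()))
        rows.append(
            {
                "p": p,
                "mean_S": float(np.mean(vals)),
                "sd_S": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)
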