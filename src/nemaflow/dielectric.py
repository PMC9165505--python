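"""Frequency-dependent dielectric response of a dual-frequency nematic.

The long-axis permittivity follows a single-relaxation (Debye-type) law

    eps_par(omega) = eps_par_inf + (eps_par_0 - eps_par_inf) / (1 + (omega * tau)**2)

while the short-axis permittivity ``eps_perp`` is frequency independent, so the
dielectric anisotropy ``delta_eps = eps_par - eps_perp`` changes sign at a
single angular frequency ``omega_0`` whenever
``eps_par_inf < eps_perp < eps_par_0``.

All frequencies are angular frequencies in s^-1; permittivities are relative
(dimensionless). No 2*pi conversion is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "DielectricParams",
    "DebyeParams",
    "NoZeroCrossingError",
    "eps_parallel",
    "delta_eps",
    "zero_crossing",
    "debye_eps",
    "freedericksz_satisfied",
]

ArrayLike = Union[float, np.ndarray]


class NoZeroCrossingError(ValueError):
    """Raised when the anisotropy has no sign change on (0, inf)."""


@dataclass(frozen=True)
class DielectricParams:
    """Relaxation constants of the dual-frequency material.

    Parameters
    ----------
    eps_par_0 : float
        Long-axis relative permittivity at omega = 0.
    eps_par_inf : float
        Long-axis relative permittivity for omega -> inf.
    eps_perp : float
        Short-axis relative permittivity (frequency independent).
    tau : float
        Dipole relaxation time in seconds.
    """

    eps_par_0: float = 0.5
    eps_par_inf: float = 0.01
    eps_perp: float = 0.2
    tau: float = 0.6

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.eps_par_0 <= self.eps_par_inf:
            raise ValueError(
                "eps_par_0 must exceed eps_par_inf "
                f"(got {self.eps_par_0} <= {self.eps_par_inf})"
            )

    @property
    def has_zero_crossing(self) -> bool:
        """True when eps_par_inf < eps_perp < eps_par_0 (finite crossing)."""
        return self.eps_par_inf < self.eps_perp < self.eps_par_0

    @classmethod
    def from_dict(cls, d: dict) -> "DielectricParams":
        known = {"eps_par_0", "eps_par_inf", "eps_perp", "tau"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown dielectric keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class DebyeParams:
    """Constants of the scalar Debye relaxation law (isotropic variant)."""

    eps_0: float
    eps_inf: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.eps_0 <= self.eps_inf:
            raise ValueError(
                f"eps_0 must exceed eps_inf (got {self.eps_0} <= {self.eps_inf})"
            )


def _check_omega(omega: ArrayLike) -> np.ndarray:
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be non-negative (angular frequency)")
    return w


def eps_parallel(params: DielectricParams, omega: ArrayLike) -> ArrayLike:
    """Long-axis permittivity at angular frequency ``omega``.

    Strictly decreasing in omega; bounded in (eps_par_inf, eps_par_0].
    """
    w = _check_omega(omega)
    out = params.eps_par_inf + (params.eps_par_0 - params.eps_par_inf) / (
        1.0 + (w * params.tau) ** 2
    )
    return out if out.ndim else float(out)


def delta_eps(params: DielectricParams, omega: ArrayLike) -> ArrayLike:
    """Dielectric anisotropy eps_par(omega) - eps_perp."""
    ep = eps_parallel(params, omega)
    out = np.asarray(ep) - params.eps_perp
    return out if out.ndim else float(out)


def zero_crossing(params: DielectricParams) -> float:
    """Angular frequency omega_0 at which the anisotropy changes sign.

    Closed form: ``omega_0 = (1/tau) * sqrt((eps_par_0 - eps_par_inf)
    / (eps_perp - eps_par_inf) - 1)``. Requires
    ``eps_par_inf < eps_perp <= eps_par_0``; the degenerate case
    ``eps_perp == eps_par_0`` yields omega_0 = 0.
    """
    if not (params.eps_par_inf < params.eps_perp <= params.eps_par_0):
        raise NoZeroCrossingError(
            "delta_eps has no zero-crossing: need "
            f"eps_par_inf < eps_perp <= eps_par_0, got "
            f"{params.eps_par_inf}, {params.eps_perp}, {params.eps_par_0}"
        )
    ratio = (params.eps_par_0 - params.eps_par_inf) / (
        params.eps_perp - params.eps_par_inf
    )
    return float(np.sqrt(ratio - 1.0) / params.tau)


def debye_eps(params: DebyeParams, omega: ArrayLike) -> ArrayLike:
    """Scalar Debye permittivity with a Lorentz local-field factor.

    Implements

        eps(omega) = eps_inf + (eps_0 - eps_inf)
                     / (1 + [((eps_0 + 2)/(eps_inf + 2)) * omega * tau]**2)

    Monotone decreasing from eps_0 at omega = 0 toward eps_inf.
    """
    w = _check_omega(omega)
    factor = (params.eps_0 + 2.0) / (params.eps_inf + 2.0)
    out = params.eps_inf + (params.eps_0 - params.eps_inf) / (
        1.0 + (factor * w * params.tau) ** 2
    )
    return out if out.ndim else float(out)


def freedericksz_satisfied(
    delta_eps_value: float, d: float, R1: float, E: float
) -> bool:
    """Whether the field exceeds the Freedericksz reorientation threshold.

    The condition is ``(d**2 / pi**2) * (|delta_eps| / R1) >= 1 / E**2`` with
    ``d`` the domain size, ``R1`` the elastic modulus and ``E`` the field
    magnitude (all in model units). The absolute value covers the
    negative-anisotropy (perpendicular) branch; zero anisotropy never
    satisfies the condition.
    """
    if d <= 0 or R1 <= 0 or E <= 0:
        raise ValueError("d, R1 and E must all be positive")
    if delta_eps_value == 0:
        return False
    lhs = (d**2 / np.pi**2) * (abs(delta_eps_value) / R1)
    return bool(lhs >= 1.0 / E**2)
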