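"""Dipolar coupling tensors and methyl order-parameter algebra.

The heteronuclear 1H,13C dipolar interaction is described by a traceless
second-rank tensor, written in its principal axis frame as

    D = delta_aniso * diag(1 - eta, 1 + eta, -2)

with anisotropy ``delta_aniso`` (Hz, signed) and asymmetry ``eta`` in [0, 1].
The rigid-limit anisotropy for an internuclear distance r is

    delta_aniso = -S * mu0 * hbar / (8 pi^2) * gamma_i * gamma_j / r^3

Fast methyl rotation about the local threefold axis scales the coupling by
P2(cos theta); slower motion of the axis itself contributes an additional
axis order parameter, so that S_met^2 = S_f^2 * S_axis^2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CODATA2018, PhysicalConstants

__all__ = [
    "DipolarTensor",
    "OrderParameters",
    "build_tensor",
    "rigid_limit_anisotropy",
    "methyl_rotation_order",
    "order_from_fit",
    "IDEAL_TETRAHEDRAL_DEG",
    "METHYL_CH_BOND_NMR",
]

#: Effective 1H,13C bond length (Angstrom) used for the methyl rigid limit.
METHYL_CH_BOND_NMR = 1.115

#: arccos(-1/3) in degrees; gives S_f^2 = 1/9 exactly.
IDEAL_TETRAHEDRAL_DEG = math.degrees(math.acos(-1.0 / 3.0))


@dataclass(frozen=True)
class DipolarTensor:
    """Traceless second-rank dipolar tensor in its principal axis frame."""

    delta_aniso: float  # Hz, signed
    eta: float  # dimensionless, in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if not np.isfinite(self.delta_aniso):
            raise ValueError("delta_aniso must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 principal-axis representation delta * diag(1-eta, 1+eta, -2)."""
        d, e = self.delta_aniso, self.eta
        xx = d * (1.0 - e)
        yy = d * (1.0 + e)
        # zz as -(xx + yy) keeps the trace exactly zero in floating point
        return np.diag([xx, yy, -(xx + yy)])


@dataclass(frozen=True)
class OrderParameters:
    """Methyl order parameters: S_met^2 = S_f^2 * S_axis^2."""

    S_met: float
    S_axis_sq: float
    S_f_sq: float
    constants: PhysicalConstants = field(default=CODATA2018, compare=False)

    def __post_init__(self):
        for name in ("S_met", "S_axis_sq", "S_f_sq"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")


def build_tensor(delta_aniso: float, eta: float) -> DipolarTensor:
    """Construct a :class:`DipolarTensor`; raises if eta is out of range."""
    return DipolarTensor(float(delta_aniso), float(eta))


def rigid_limit_anisotropy(
    r: float,
    constants: PhysicalConstants = CODATA2018,
    S: float = 1.0,
    gamma_i: float | None = None,
    gamma_j: float | None = None,
) -> float:
    """Rigid-limit dipolar coupling anisotropy in Hz for distance ``r`` (Angstrom).

    Defaults to the heteronuclear 1H,13C pair. The leading minus sign of the
    standard expression is kept, so the returned value is negative for
    positive gyromagnetic ratios.
    """
    if r <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r}")
    gi = constants.gamma_H if gamma_i is None else gamma_i
    gj = constants.gamma_C if gamma_j is None else gamma_j
    r_m = r * 1e-10
    return -S * constants.mu0 * constants.hbar / (8.0 * math.pi**2) * gi * gj / r_m**3


def methyl_rotation_order(theta: float) -> float:
    """S_f^2 = {P2(cos theta)}^2 for a proton at angle ``theta`` (degrees)
    from the methyl rotation axis.

    Equals 1/9 at the ideal tetrahedral half-angle arccos(-1/3) = 109.471 deg.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must lie in [0, 180] degrees, got {theta}")
    c = math.cos(math.radians(theta))
    p2 = 0.5 * (3.0 * c * c - 1.0)
    return p2 * p2


def order_from_fit(
    delta_fit: float,
    r: float = METHYL_CH_BOND_NMR,
    S_f_sq: float = 1.0 / 9.0,
    constants: PhysicalConstants = CODATA2018,
) -> OrderParameters:
    """Convert a fitted anisotropy into order parameters.

    S_met = |delta_fit| / |rigid-limit anisotropy at r|, and
    S_axis^2 = S_met^2 / S_f^2. Raises if the fitted coupling exceeds the
    rigid limit (S_met > 1) beyond numerical tolerance.
    """
    rigid = rigid_limit_anisotropy(r, constants=constants)
    if rigid == 0.0:
        raise ValueError("rigid-limit anisotropy is zero")
    s_met = abs(delta_fit / rigid)
    if s_met > 1.0 + 1e-6:
        raise ValueError(
            f"fitted |anisotropy| {abs(delta_fit):.1f} Hz exceeds the rigid "
            f"limit {abs(rigid):.1f} Hz (S_met={s_met:.4f})"
        )
    if S_f_sq <= 0:
        raise ValueError("S_f_sq must be positive")
    s_axis_sq = s_met**2 / S_f_sq
    if s_axis_sq > 1.0 + 1e-6:
        raise ValueError(
            f"S_axis^2 = {s_axis_sq:.4f} > 1: fitted coupling inconsistent "
            "with the fast-rotation scaling"
        )
    return OrderParameters(
        S_met=min(s_met, 1.0),
        S_axis_sq=min(s_axis_sq, 1.0),
        S_f_sq=S_f_sq,
        constants=constants,
    )
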