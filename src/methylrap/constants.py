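"""Physical constants used throughout the package.

All dipolar-coupling prefactors trace back to a single named CODATA release so
that every result file can record exactly which constant set produced it.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants entering the dipolar-coupling prefactor.

    Attributes
    ----------
    name : str
        Label of the constant set (recorded in output metadata).
    mu0 : float
        Magnetic constant, N A^-2.
    hbar : float
        Reduced Planck constant, J s.
    gamma_H : float
        1H gyromagnetic ratio, rad s^-1 T^-1.
    gamma_C : float
        13C gyromagnetic ratio, rad s^-1 T^-1.
    """

    name: str = "CODATA2018"
    mu0: float = 1.25663706212e-6
    hbar: float = 1.054571817e-34
    gamma_H: float = 2.6752218744e8
    gamma_C: float = 6.728284e7

    def as_dict(self) -> dict:
        return asdict(self)


CODATA2018 = PhysicalConstants()
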