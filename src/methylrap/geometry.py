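"""Small vector-geometry helpers for building ideal sp3 hydrogen positions."""
from __future__ import annotations

import numpy as np

#: build length for constructed C-H bonds (Angstrom); distinct from the
#: effective 1.115 A NMR bond length used only in the rigid-limit coupling.
CH_BUILD_LENGTH = 1.09

#: cos of the angle between a methyl C-H direction and the (parent->C) axis
#: equals 1/3 exactly, which makes all H-C-H angles arccos(-1/3).
_COS_AXIS = 1.0 / 3.0
_SIN_AXIS = np.sqrt(1.0 - _COS_AXIS**2)


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def perp_frame(axis: np.ndarray, ref: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (and to each other)."""
    axis = unit(axis)
    if ref is None or abs(np.dot(unit(ref), axis)) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
    u1 = unit(ref - np.dot(ref, axis) * axis)
    u2 = np.cross(axis, u1)
    return u1, u2


def methyl_hydrogens(
    c_pos: np.ndarray,
    parent_pos: np.ndarray,
    ref: np.ndarray | None = None,
    bond: float = CH_BUILD_LENGTH,
    phase: float = 0.0,
) -> np.ndarray:
    """Three ideal-tetrahedral H positions for a methyl carbon.

    The H directions make arccos(1/3) with the parent->carbon axis, spaced
    120 degrees; every H-C-H angle is exactly arccos(-1/3).
    """
    axis = unit(np.asarray(c_pos) - np.asarray(parent_pos))
    u1, u2 = perp_frame(axis, ref)
    out = np.empty((3, 3))
    for i in range(3):
        phi = phase + 2.0 * np.pi * i / 3.0
        d = _COS_AXIS * axis + _SIN_AXIS * (np.cos(phi) * u1 + np.sin(phi) * u2)
        out[i] = np.asarray(c_pos) + bond * d
    return out


def tetra_directions(
    center: np.ndarray,
    parent_pos: np.ndarray,
    ref: np.ndarray | None = None,
    phase: float = 0.0,
) -> np.ndarray:
    """Three unit vectors tetrahedrally arranged opposite the parent atom."""
    pts = methyl_hydrogens(center, parent_pos, ref=ref, bond=1.0, phase=phase)
    return pts - np.asarray(center)[None, :]


def tetra_substituents(
    center: np.ndarray,
    parent_pos: np.ndarray,
    n: int,
    length: float,
    ref: np.ndarray | None = None,
    phase: float = 0.0,
) -> np.ndarray:
    """``n`` (<=3) substituent positions tetrahedrally arranged around
    ``center`` opposite the parent atom."""
    pts = methyl_hydrogens(center, parent_pos, ref=ref, bond=length, phase=phase)
    return pts[:n]
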