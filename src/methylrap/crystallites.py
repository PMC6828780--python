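"""Powder-averaging crystallite orientation sets.

Orientations are (alpha, beta, gamma) ZYZ Euler angles carrying the dipolar
tensor from its principal axis frame into the rotor frame; gamma doubles as
the initial rotor phase. Two deterministic (alpha, beta) constructions are
provided:

``zcw``
    Fibonacci/golden-ratio set: cos(beta) uniformly stratified over the full
    sphere, alpha stepped by the golden ratio (the ZCW-type construction).
``repulsion``
    Points relaxed on the sphere by a fixed number of pairwise-repulsion
    iterations from a spherical-Fibonacci start (REPULSION-type set).

Both are equal-weight and reproducible for a given (scheme, count).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CrystalliteSet", "make_crystallites"]

_GOLDEN = (1.0 + 5.0**0.5) / 2.0


@dataclass(frozen=True)
class CrystalliteSet:
    """Euler angles (M, 3) in radians with normalized weights (M,)."""

    angles: np.ndarray
    weights: np.ndarray
    scheme: str = "custom"

    def __post_init__(self):
        ang = np.asarray(self.angles, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if ang.ndim != 2 or ang.shape[1] != 3:
            raise ValueError("angles must have shape (M, 3)")
        if w.shape != (ang.shape[0],):
            raise ValueError("weights must have shape (M,)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.angles.shape[0]


def _zcw_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    j = np.arange(n)
    beta = np.arccos(1.0 - 2.0 * (j + 0.5) / n)
    alpha = 2.0 * np.pi * np.mod(j / _GOLDEN, 1.0)
    return alpha, beta


def _repulsion_pairs(n: int, n_iter: int = 40) -> tuple[np.ndarray, np.ndarray]:
    # spherical-Fibonacci start, then tangential pairwise repulsion
    alpha, beta = _zcw_pairs(n)
    xyz = np.stack(
        [np.sin(beta) * np.cos(alpha), np.sin(beta) * np.sin(alpha), np.cos(beta)],
        axis=1,
    )
    step = 0.1
    for _ in range(n_iter):
        diff = xyz[:, None, :] - xyz[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        force = np.sum(diff / d2[..., None] ** 1.5, axis=1)
        xyz = xyz + step * force / n
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    beta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    alpha = np.mod(np.arctan2(xyz[:, 1], xyz[:, 0]), 2.0 * np.pi)
    return alpha, beta


def make_crystallites(
    scheme_name: str = "zcw", n_orientations: int = 377, n_gamma: int = 18
) -> CrystalliteSet:
    """Build an equal-weight crystallite set of n_orientations x n_gamma angles."""
    if n_orientations < 1 or n_gamma < 1:
        raise ValueError("n_orientations and n_gamma must be >= 1")
    scheme = scheme_name.lower()
    if scheme == "zcw":
        alpha, beta = _zcw_pairs(n_orientations)
    elif scheme == "repulsion":
        alpha, beta = _repulsion_pairs(n_orientations)
    elif scheme == "single":
        alpha, beta = np.zeros(n_orientations), np.zeros(n_orientations)
    else:
        raise ValueError(f"unknown crystallite scheme {scheme_name!r}")
    gamma = 2.0 * np.pi * np.arange(n_gamma) / n_gamma
    a = np.repeat(alpha, n_gamma)
    b = np.repeat(beta, n_gamma)
    g = np.tile(gamma, n_orientations)
    angles = np.stack([a, b, g], axis=1)
    m = angles.shape[0]
    return CrystalliteSet(angles=angles, weights=np.full(m, 1.0 / m), scheme=scheme)
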