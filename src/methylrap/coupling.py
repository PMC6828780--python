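"""Effective 1H,1H dipolar couplings, contact maps and cross-peak statistics.

For every methyl proton site j and labelling replica l the effective
homonuclear coupling is the root-sum-square over all occupied protons k
within a distance cutoff,

    d_j = (1/N) sum_l sqrt( sum_{k != j} d_jkl^2 ),

with d_j(l) = 0 when site j itself is unoccupied in replica l. Couplings
between protons of the same methyl group are scaled by |P2(cos 90 deg)| =
0.5 (fast methyl rotation). The pair coupling magnitude follows the same
prefactor as the heteronuclear anisotropy with both gyromagnetic ratios
equal to gamma_H:  d(r) = mu0 hbar gamma_H^2 / (8 pi^2 r^3).

Contact maps report, per residue pair, the fraction of replicas in which at
least one occupied 1H,1H pair lies within the cutoff (default 5 A). The
cross-peak probability for N adjoining sites of per-site probability p is
the binomial tail P(X >= 2) and the number of distinct cross-peak
combinations is 2^N - N - 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CODATA2018, PhysicalConstants
from .labelling import LabelledEnsemble

__all__ = [
    "EffectiveCouplingResult",
    "ContactMap",
    "pair_coupling",
    "effective_coupling",
    "contact_map",
    "cross_peak_probability",
    "n_pair_combinations",
]

INTRA_METHYL_SCALE = 0.5  # |P2(cos 90 deg)|


def pair_coupling(r: float, constants: PhysicalConstants = CODATA2018) -> float:
    """Homonuclear 1H,1H dipolar coupling magnitude (Hz) at distance r (A)."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("distance must be positive")
    r_m = np.asarray(r, dtype=float) * 1e-10
    out = constants.mu0 * constants.hbar * constants.gamma_H**2 / (
        8.0 * np.pi**2 * r_m**3
    )
    return float(out) if np.isscalar(r) else out


@dataclass(frozen=True)
class EffectiveCouplingResult:
    """Ensemble statistics of the effective coupling at one methyl site."""

    site_id: str
    d_mean: float  # Hz
    sd: float  # Hz, Bessel-corrected sd of the replica distribution
    upper_2sigma: float  # d_mean + 2 sd
    n_replicas: int
    sem: float = 0.0  # sd / sqrt(N), recorded for reference


def _coupling_matrix(
    coords: np.ndarray,
    group_ids: list,
    cutoff: float,
    intra_methyl_scale: float,
    constants: PhysicalConstants,
) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(r, np.inf)
    d = np.where(r <= cutoff, pair_coupling(np.where(r <= cutoff, r, 1.0),
                                            constants), 0.0)
    gid = np.array([g if g is not None else f"__none{i}"
                    for i, g in enumerate(group_ids)])
    same = gid[:, None] == gid[None, :]
    d = np.where(same, d * intra_methyl_scale, d)
    np.fill_diagonal(d, 0.0)
    return d


def effective_coupling(
    ensemble: LabelledEnsemble,
    cutoff: float = 10.0,
    intra_methyl_scale: float = INTRA_METHYL_SCALE,
    constants: PhysicalConstants = CODATA2018,
) -> list[EffectiveCouplingResult]:
    """Per-methyl-site ensemble mean and spread of the effective coupling."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sites = ensemble.sites
    coords = np.array([s.coords for s in sites])
    group_ids = [s.methyl_group_id for s in sites]
    d = _coupling_matrix(coords, group_ids, cutoff, intra_methyl_scale, constants)
    d2 = d**2
    methyl_idx = [i for i, s in enumerate(sites) if s.site_class == "methyl"]
    occ = ensemble.occupancy.astype(float)
    # sum over occupied partners k of d_jk^2 (d_jj = 0)
    sums = occ @ d2[:, methyl_idx]  # (n_rep, n_methyl)
    vals = np.sqrt(sums) * occ[:, methyl_idx]
    n = occ.shape[0]
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1) if n > 1 else np.zeros_like(means)
    out = []
    for c, j in enumerate(methyl_idx):
        out.append(
            EffectiveCouplingResult(
                site_id=sites[j].site_id,
                d_mean=float(means[c]),
                sd=float(sds[c]),
                upper_2sigma=float(means[c] + 2.0 * sds[c]),
                n_replicas=n,
                sem=float(sds[c] / np.sqrt(n)),
            )
        )
    return out


@dataclass
class ContactMap:
    """Residue-pair 1H,1H contact frequencies in [0, 1] (symmetric)."""

    frequencies: np.ndarray  # (R, R)
    residue_labels: list  # (chain, residue_index, residue_type)
    distance_cutoff: float
    scheme_name: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        labels = [f"{c}:{t}{i}" for c, i, t in self.residue_labels]
        R = len(labels)
        for a in range(R):
            for b in range(a, R):
                f = self.frequencies[a, b]
                if f > 0:
                    rows.append({"res_i": labels[a], "res_j": labels[b],
                                 "frequency": f})
        return pd.DataFrame(rows, columns=["res_i", "res_j", "frequency"])


def contact_map(
    ensemble: LabelledEnsemble, cutoff: float = 5.0
) -> ContactMap:
    """Fraction of replicas with >= 1 occupied 1H pair within ``cutoff`` A
    for every residue pair (intra-residue pairs included on the diagonal)."""
    sites = ensemble.sites
    coords = np.array([s.coords for s in sites])
    res_keys = []
    res_index = {}
    site_res = np.empty(len(sites), dtype=int)
    for i, s in enumerate(sites):
        key = (s.chain, s.residue_index, s.residue_type)
        if key not in res_index:
            res_index[key] = len(res_keys)
            res_keys.append(key)
        site_res[i] = res_index[key]
    diff = coords[:, None, :] - coords[None, :, :]
    rr = np.sqrt(np.sum(diff**2, axis=-1))
    a_idx, b_idx = np.nonzero(np.triu(rr <= cutoff, k=1))
    occ = ensemble.occupancy
    n_rep = occ.shape[0]
    R = len(res_keys)
    freq = np.zeros((R, R))
    pair_res = {}
    for a, b in zip(a_idx, b_idx):
        key = (min(site_res[a], site_res[b]), max(site_res[a], site_res[b]))
        pair_res.setdefault(key, []).append((a, b))
    for (ri, rj), pairs in pair_res.items():
        hit = np.zeros(n_rep, dtype=bool)
        for a, b in pairs:
            hit |= occ[:, a] & occ[:, b]
        f = hit.mean()
        freq[ri, rj] = f
        freq[rj, ri] = f
    return ContactMap(freq, res_keys, cutoff, ensemble.scheme.name)


def cross_peak_probability(N: int, p: float) -> float:
    """Probability of >= 2 protonated sites among N adjoining sites,
    P = sum_{i=2}^{N} C(N, i) p^i (1-p)^(N-i) = 1 - (1-p)^N - N p (1-p)^(N-1)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    return 1.0 - q**N - N * p * q ** (N - 1)


def n_pair_combinations(N: int) -> int:
    """Number of cross-peak combinations among N sites: 2^N - N - 1."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return 2**N - N - 1
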