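"""Synthetic protein structures and noisy REDOR datasets for testing.

The structure generator produces coarse ideal-geometry chains of the
methyl-bearing residue types (A, I, L, M, T, V) plus G, with explicit
hydrogens built at exact ideal sp3 geometry. Folds:

``helix``          -- CA trace on an alpha-helical spiral, side chains radial
``extended``       -- CA trace on a line, side chains alternating up/down
``clustered_core`` -- compact globule with every side chain pointing at the
                      common centroid: Leu/Val methyl tips bundle on an inner
                      sphere (emulating the spatial clustering of Leu/Val in a
                      hydrophobic core), other side chains form a second shell
                      and the backbone envelops the whole

These are geometric stand-ins, not physical models: only the inter-proton
distance statistics matter for the analyses they exercise.

The REDOR dataset generator is the forward model of the experimental
pipeline: a true dephasing fraction from the delta-pulse powder simulation,
an apparent exponential decay applied to S and S0 alike (cancelled by the
(S0-S)/S0 construction), sparse reference sampling, and Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystallites import make_crystallites
from .fitting import PeakVolumeTable
from .geometry import CH_BUILD_LENGTH, methyl_hydrogens, tetra_directions, unit
from .redor import SequenceParams, _delta_phase_factors, _delta_pulse_fraction
from .structure import ProteinStructure

__all__ = [
    "SyntheticStructureSpec",
    "SyntheticRedorSpec",
    "make_structure",
    "make_redor_dataset",
]

_ONE_TO_THREE = {"A": "ALA", "I": "ILE", "L": "LEU", "M": "MET",
                 "T": "THR", "V": "VAL", "G": "GLY"}

_CC = 1.53
_CO = 1.42
_CS = 1.81
_OH = 0.96


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Recipe for a synthetic multi-copy structure."""

    n_residues: int
    sequence: str
    fold: str = "extended"  # helix | extended | clustered_core
    n_copies: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        bad = set(self.sequence) - set(_ONE_TO_THREE)
        if bad:
            raise ValueError(f"unsupported residue letters: {sorted(bad)}")
        if self.fold not in ("helix", "extended", "clustered_core"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


def _fibonacci_sphere(n: int, offset: float = 0.0) -> np.ndarray:
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / max(n, 1)
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.stack(
        [rho * np.cos(golden * k + offset), rho * np.sin(golden * k + offset), z],
        axis=1,
    )


def _backbone_frames(spec: SyntheticStructureSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CA positions, chain tangents and side-chain directions per residue."""
    n = spec.n_residues
    if spec.fold == "extended":
        ca = np.stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
        t = np.tile([1.0, 0.0, 0.0], (n, 1))
        d = np.stack([np.zeros(n), np.zeros(n),
                      np.where(np.arange(n) % 2 == 0, 1.0, -1.0)], axis=1)
    elif spec.fold == "helix":
        theta = np.radians(100.0) * np.arange(n)
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                       1.5 * np.arange(n)], axis=1)
        tang = np.stack([-np.sin(theta), np.cos(theta),
                         np.full(n, 1.5 / (2.3 * np.radians(100.0)))], axis=1)
        t = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        d = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    else:  # clustered_core
        # Compact globule: every side chain points at the common centroid.
        # Leu/Val methyl tips sit on an inner sphere with ~5 A spacing (the
        # typical CH3...CH3 packing contact of hydrophobic cores, pairwise
        # tip distances well under 6 A for moderate counts); the remaining
        # residues form a second tip shell one van-der-Waals methyl layer
        # further out, with the backbone (and its amide H) enveloping the
        # whole, as in a folded protein.
        core = np.array([c in "LV" for c in spec.sequence])
        n_core = int(core.sum())
        n_out = n - n_core
        r1 = max(2.4, 5.0 * np.sqrt(max(n_core, 1) / (4.0 * np.pi)))
        r2 = max(r1 + 3.5, 4.5 * np.sqrt(max(n_out, 1) / (4.0 * np.pi)))
        # CA -> methyl-tip reach per residue type
        ext = np.array(
            [{"V": 2.6, "L": 3.7, "I": 3.9, "M": 4.9, "T": 2.5, "A": 2.2,
              "G": 1.1}[c] for c in spec.sequence]
        )
        dirs = np.empty((n, 3))
        dirs[core] = _fibonacci_sphere(n_core)
        dirs[~core] = _fibonacci_sphere(n_out, offset=np.pi / 5.0)
        r_tip = np.where(core, r1, r2)
        ca = dirs * (r_tip + ext)[:, None]
        d = -dirs
        # chain tangent: any unit vector perpendicular to the side direction
        zhat = np.tile([0.0, 0.0, 1.0], (n, 1))
        zhat[np.abs(d[:, 2]) > 0.9] = [1.0, 0.0, 0.0]
        t = np.cross(d, zhat)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    return ca, t, d


class _Builder:
    def __init__(self):
        self.names, self.elements, self.res_names = [], [], []
        self.res_seqs, self.chains, self.coords = [], [], []

    def add(self, name, element, res_name, res_seq, chain, pos):
        self.names.append(name)
        self.elements.append(element)
        self.res_names.append(res_name)
        self.res_seqs.append(res_seq)
        self.chains.append(chain)
        self.coords.append(np.asarray(pos, dtype=float))

    def methyl(self, carbon_name, c_pos, parent_pos, res_name, res_seq, chain, rng):
        h = methyl_hydrogens(c_pos, parent_pos, phase=rng.uniform(0, 2 * np.pi),
                             bond=CH_BUILD_LENGTH)
        base = "H" + carbon_name[1:]
        for k in range(3):
            self.add(f"{base}{k + 1}", "H", res_name, res_seq, chain, h[k])


def _build_sidechain(b: _Builder, rname, rs, ch, ca, t, d, u, rng,
                     phase=0.0):
    """Grow side-chain heavy atoms and H from CA along direction d.

    ``phase`` sets the azimuth of the heavy-atom branching around the
    side-chain axis; make_structure picks it per residue to avoid clashes.
    """
    if rname == "GLY":
        b.add("HA2", "H", rname, rs, ch, ca + CH_BUILD_LENGTH * unit(d))
        b.add("HA3", "H", rname, rs, ch, ca - CH_BUILD_LENGTH * u)
        return
    b.add("HA", "H", rname, rs, ch, ca - CH_BUILD_LENGTH * u)
    cb = ca + _CC * unit(d)
    b.add("CB", "C", rname, rs, ch, cb)
    if rname == "ALA":
        b.methyl("CB", cb, ca, rname, rs, ch, rng)
        return
    dirs = tetra_directions(cb, ca, ref=u, phase=phase)
    if rname == "VAL":
        cg1, cg2 = cb + _CC * dirs[0], cb + _CC * dirs[1]
        b.add("CG1", "C", rname, rs, ch, cg1)
        b.add("CG2", "C", rname, rs, ch, cg2)
        b.add("HB", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[2])
        b.methyl("CG1", cg1, cb, rname, rs, ch, rng)
        b.methyl("CG2", cg2, cb, rname, rs, ch, rng)
    elif rname == "LEU":
        cg = cb + _CC * dirs[0]
        b.add("CG", "C", rname, rs, ch, cg)
        b.add("HB2", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[1])
        b.add("HB3", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[2])
        dg = tetra_directions(cg, cb, ref=u, phase=phase)
        cd1, cd2 = cg + _CC * dg[0], cg + _CC * dg[1]
        b.add("CD1", "C", rname, rs, ch, cd1)
        b.add("CD2", "C", rname, rs, ch, cd2)
        b.add("HG", "H", rname, rs, ch, cg + CH_BUILD_LENGTH * dg[2])
        b.methyl("CD1", cd1, cg, rname, rs, ch, rng)
        b.methyl("CD2", cd2, cg, rname, rs, ch, rng)
    elif rname == "ILE":
        cg1, cg2 = cb + _CC * dirs[0], cb + _CC * dirs[1]
        b.add("CG1", "C", rname, rs, ch, cg1)
        b.add("CG2", "C", rname, rs, ch, cg2)
        b.add("HB", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[2])
        b.methyl("CG2", cg2, cb, rname, rs, ch, rng)
        dg = tetra_directions(cg1, cb, ref=u, phase=phase)
        cd1 = cg1 + _CC * dg[0]
        b.add("CD1", "C", rname, rs, ch, cd1)
        b.add("HG12", "H", rname, rs, ch, cg1 + CH_BUILD_LENGTH * dg[1])
        b.add("HG13", "H", rname, rs, ch, cg1 + CH_BUILD_LENGTH * dg[2])
        b.methyl("CD1", cd1, cg1, rname, rs, ch, rng)
    elif rname == "THR":
        og1 = cb + _CO * dirs[0]
        cg2 = cb + _CC * dirs[1]
        b.add("OG1", "O", rname, rs, ch, og1)
        b.add("CG2", "C", rname, rs, ch, cg2)
        b.add("HB", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[2])
        b.add("HG1", "H", rname, rs, ch, og1 + _OH * unit(dirs[0]))
        b.methyl("CG2", cg2, cb, rname, rs, ch, rng)
    elif rname == "MET":
        cg = cb + _CC * dirs[0]
        b.add("CG", "C", rname, rs, ch, cg)
        b.add("HB2", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[1])
        b.add("HB3", "H", rname, rs, ch, cb + CH_BUILD_LENGTH * dirs[2])
        dg = tetra_directions(cg, cb, ref=u, phase=phase)
        sd = cg + _CS * dg[0]
        b.add("SD", "S", rname, rs, ch, sd)
        b.add("HG2", "H", rname, rs, ch, cg + CH_BUILD_LENGTH * dg[1])
        b.add("HG3", "H", rname, rs, ch, cg + CH_BUILD_LENGTH * dg[2])
        ds = tetra_directions(sd, cg, ref=u, phase=phase)
        ce = sd + _CS * ds[0]
        b.add("CE", "C", rname, rs, ch, ce)
        b.methyl("CE", ce, sd, rname, rs, ch, rng)


def make_structure(spec: SyntheticStructureSpec) -> ProteinStructure:
    """Build a synthetic structure with classified proton sites."""
    rng = np.random.default_rng(spec.seed)
    ca0, t0, d0 = _backbone_frames(spec)
    copies = []
    for c in range(spec.n_copies):
        b = _Builder()
        ch = chr(ord("A") + c)
        for i in range(spec.n_residues):
            rname = _ONE_TO_THREE[spec.sequence[i]]
            rs = i + 1
            ca, t, d = ca0[i], t0[i], d0[i]
            u = np.cross(t, d)
            if np.linalg.norm(u) < 1e-6:
                u = np.array([0.0, 1.0, 0.0])
            u = unit(u)
            n_res_start = len(b.names)
            existing0 = np.array(b.coords) if b.coords else None
            # backbone occupies the +u lane; side chains keep the d lane.
            # The (t, u) frame may rotate about d in 90-degree steps: pick
            # the orientation keeping the backbone farthest from earlier
            # residues (greedy clash avoidance).
            best_bb, best_bb_score = None, -np.inf
            for psi in np.radians(np.arange(0.0, 360.0, 45.0)):
                t2 = np.cos(psi) * t + np.sin(psi) * u
                u2 = -np.sin(psi) * t + np.cos(psi) * u
                # N and C tilt away from the side chain (tetrahedral-like
                # angles at CA keep amide H clear of the side-chain H)
                npos = ca + 1.45 * unit(-0.68 * t2 + 0.48 * u2 - 0.55 * d)
                cpos = ca + 1.52 * unit(0.68 * t2 + 0.48 * u2 - 0.55 * d)
                bb = np.array([npos, npos + 1.01 * unit(npos - ca), ca,
                               cpos, cpos + 1.23 * u2])
                if existing0 is not None:
                    score = np.min(np.linalg.norm(
                        bb[:, None, :] - existing0[None, :, :], axis=-1))
                else:
                    score = 0.0
                if score > best_bb_score + 1e-9:
                    best_bb, best_bb_score = (t2, u2, npos, cpos), score
            t, u, npos, cpos = best_bb
            b.add("N", "N", rname, rs, ch, npos)
            b.add("H", "H", rname, rs, ch, npos + 1.01 * unit(npos - ca))
            b.add("CA", "C", rname, rs, ch, ca)
            b.add("C", "C", rname, rs, ch, cpos)
            b.add("O", "O", rname, rs, ch, cpos + 1.23 * u)
            # greedy clash avoidance: pick the branch azimuth (and the
            # deterministic methyl phases tied to it) that keeps this
            # residue's side chain farthest from everything already built,
            # its own backbone included (CA excluded: bonded to CB)
            n_before = len(b.names)
            existing = np.array(
                [xyz for k2, xyz in enumerate(b.coords[:n_before])
                 if k2 != n_res_start + 2]
            ) if n_before else None
            best_phase, best_score = 0, -np.inf
            for cand in range(0, 360, 30):
                trial_rng = np.random.default_rng((spec.seed, i, cand))
                _build_sidechain(b, rname, rs, ch, ca, t, d, u, trial_rng,
                                 phase=np.radians(cand))
                new = np.array(b.coords[n_before:])
                del b.names[n_before:], b.elements[n_before:]
                del b.res_names[n_before:], b.res_seqs[n_before:]
                del b.chains[n_before:], b.coords[n_before:]
                if existing is not None and new.shape[0]:
                    score = np.min(np.linalg.norm(
                        new[:, None, :] - existing[None, :, :], axis=-1))
                else:
                    score = 0.0
                if score > best_score + 1e-9:
                    best_phase, best_score = cand, score
            final_rng = np.random.default_rng((spec.seed, i, best_phase))
            _build_sidechain(b, rname, rs, ch, ca, t, d, u, final_rng,
                             phase=np.radians(best_phase))
        copies.append(b)
    # translate copies apart along x
    all_b = _Builder()
    extent = (np.max([c[0] for c in copies[0].coords])
              - np.min([c[0] for c in copies[0].coords])) + 10.0
    for c, b in enumerate(copies):
        shift = np.array([c * extent, 0.0, 0.0])
        for nm, el, rn, rs, ch, xyz in zip(
            b.names, b.elements, b.res_names, b.res_seqs, b.chains, b.coords
        ):
            all_b.add(nm, el, rn, rs, ch, xyz + shift)
    st = ProteinStructure(
        all_b.names, all_b.elements, all_b.res_names,
        np.array(all_b.res_seqs), all_b.chains, np.array(all_b.coords),
    )
    st.proton_sites()
    return st


@dataclass(frozen=True)
class SyntheticRedorSpec:
    """Forward model of a REDOR measurement on one site."""

    true_delta: float  # Hz (signed)
    true_eta: float
    noise_sd: float = 0.0
    schedule: tuple | None = None  # dephasing times (s); default inside total
    ref_spacing: float = 0.12e-3  # s
    total_time: float = 1.92e-3  # s
    decay_rate: float = 25.0  # 1/s apparent relaxation of S and S0
    mas_rate: float = 50e3
    zeta: float = 4e-6
    seed: int = 0
    site_id: str = "SYN1"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def times(self) -> np.ndarray:
        if self.schedule is not None:
            t = np.asarray(self.schedule, dtype=float)
        else:
            tau_r = 1.0 / self.mas_rate
            n = np.arange(0, 48, 4)
            t = 2.0 * tau_r * (n + 1)
        t = t[t <= self.total_time + 1e-12]
        if t.size == 0:
            raise ValueError("schedule has no points inside total_time")
        return t


def make_redor_dataset(
    spec: SyntheticRedorSpec,
    simulator=None,
    crystallites=None,
) -> tuple[PeakVolumeTable, PeakVolumeTable]:
    """Noisy (S, S0) peak-volume tables for a known dipolar tensor.

    ``simulator``: optional callable times -> true dephasing fraction;
    the default is the delta-pulse powder simulation at the spec's MAS rate
    and shift.
    """
    times = spec.times
    if simulator is None:
        if crystallites is None:
            # gamma sampling controls powder convergence at long dephasing
            crystallites = make_crystallites("zcw", 610, 16)
        params = SequenceParams(mas_rate=spec.mas_rate, zeta=spec.zeta,
                                n_max=0, delta_pulse=True)
        PhiA, PhiB = _delta_phase_factors(params, crystallites, times)
        frac = _delta_pulse_fraction(abs(spec.true_delta), spec.true_eta,
                                     PhiA, PhiB, crystallites.weights)
    else:
        frac = np.asarray(simulator(times), dtype=float)
    rng = np.random.default_rng(spec.seed)
    t0 = np.arange(0.0, spec.total_time + 1e-12, spec.ref_spacing)
    s0_clean = np.exp(-spec.decay_rate * t0)
    s0 = s0_clean * (1.0 + rng.normal(0.0, spec.noise_sd, t0.size)) \
        if spec.noise_sd > 0 else s0_clean
    s_clean = np.exp(-spec.decay_rate * times) * (1.0 - frac)
    s = s_clean + rng.normal(0.0, spec.noise_sd, times.size) \
        if spec.noise_sd > 0 else s_clean
    S0 = PeakVolumeTable(spec.site_id, t0, s0, "S0", noise_sd=spec.noise_sd)
    S = PeakVolumeTable(spec.site_id, times, s, "S", noise_sd=spec.noise_sd)
    return S, S0
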