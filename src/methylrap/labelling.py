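"""Stochastic isotopomer labelling of protein hydrogen sites.

Three scheme kinds are modelled:

``random``
    Reduced-adjoining-protonation (RAP) style: every non-exchangeable H site
    is independently 1H with a small per-class probability (the 5% glucose
    RAP scheme averages ~3.5% at methyl sites).
``precursor``
    Leu/Val 13CHD2 alpha-ketoisovalerate labelling: per Leu/Val residue one
    of the two prochiral methyls (1/2 each) carries a single 1H on one of
    its three positions (1/3 each); all other side-chain H are 2H.
``uniform``
    Fully protonated.

Exchangeable (N/O/S-bound) sites are 1H with ``exchangeable_h_fraction``
(0 for 100% D2O buffers, 1 for full back-substitution). Replica ensembles
are reproducible from their seed. The theoretical-mass model accounts for
carbon-source impurities: residual protonation of nominally 2H positions
(default 3%) and residual 12C in the 13C-enriched source (default 1%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .structure import ProteinStructure, ProtonSite

__all__ = [
    "LabellingScheme",
    "LabelledEnsemble",
    "assign_isotopomers",
    "theoretical_mass",
    "scheme_presets",
    "expected_sensitivity_ratio",
]

# isotope / average atomic masses (Da)
MASS_1H = 1.00782503207
MASS_2H = 2.01410177785
MASS_12C = 12.0
MASS_13C = 13.00335483507
MASS_N = 14.007
MASS_O = 15.999
MASS_S = 32.06

# residue-in-chain formulas: (C, H, N, O, S) and number of exchangeable H
RESIDUE_FORMULAS = {
    "GLY": ((2, 3, 1, 1, 0), 1),
    "ALA": ((3, 5, 1, 1, 0), 1),
    "VAL": ((5, 9, 1, 1, 0), 1),
    "LEU": ((6, 11, 1, 1, 0), 1),
    "ILE": ((6, 11, 1, 1, 0), 1),
    "THR": ((4, 7, 1, 2, 0), 2),
    "MET": ((5, 9, 1, 1, 1), 1),
}


@dataclass(frozen=True)
class LabellingScheme:
    """Per-site 1H incorporation probabilities and impurity parameters."""

    name: str
    kind: str = "random"  # random | precursor | uniform
    p_methyl: float = 0.035
    p_aliphatic: float = 0.035
    p_aromatic: float = 0.035
    exchangeable_h_fraction: float = 0.0
    residual_protonation: float = 0.03
    c12_fraction: float = 0.01
    p_by_residue_type: dict = field(default_factory=dict)
    probability_scale: float = 1.0  # global rescaling (e.g. to match MALDI)

    def __post_init__(self):
        if self.kind not in ("random", "precursor", "uniform"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        for attr in ("p_methyl", "p_aliphatic", "p_aromatic",
                     "exchangeable_h_fraction", "residual_protonation",
                     "c12_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")

    def site_probability(self, site: ProtonSite) -> float:
        """Marginal 1H probability of one site (precursor methyls: 1/6)."""
        if site.site_class == "exchangeable":
            return self.exchangeable_h_fraction
        if self.kind == "uniform":
            return 1.0
        if self.kind == "precursor":
            if (site.site_class == "methyl"
                    and site.residue_type in ("LEU", "VAL")):
                return 1.0 / 6.0
            return 0.0
        p = {
            "methyl": self.p_methyl,
            "aliphatic": self.p_aliphatic,
            "aromatic": self.p_aromatic,
        }[site.site_class]
        p = self.p_by_residue_type.get(site.residue_type, p)
        return min(1.0, p * self.probability_scale)

    def as_dict(self) -> dict:
        return asdict(self)


def scheme_presets() -> dict[str, LabellingScheme]:
    """Named presets for the labelling schemes compared in this package."""
    glcrap5 = LabellingScheme(name="glcrap5", kind="random")
    leuval = LabellingScheme(name="leuval_chd2", kind="precursor")
    return {
        "glcrap5": glcrap5,
        "leuval_chd2": leuval,
        "uniform": LabellingScheme(name="uniform", kind="uniform",
                                   exchangeable_h_fraction=1.0),
        "glcrap5_backexchanged": LabellingScheme(
            name="glcrap5_backexchanged", kind="random",
            exchangeable_h_fraction=1.0),
        "leuval_backexchanged": LabellingScheme(
            name="leuval_backexchanged", kind="precursor",
            exchangeable_h_fraction=1.0),
    }


def expected_sensitivity_ratio(scheme_a: str | LabellingScheme = "leuval_chd2",
                               scheme_b: str | LabellingScheme = "glcrap5") -> float:
    """Ratio of mean methyl-site 1H probabilities of two schemes.

    The expected signal-to-noise gain of scheme A over scheme B scales with
    the methyl proton concentration ratio (1/6 : 0.035 ~ 5 for Leu/Val
    precursor labelling versus 5% glucose RAP).
    """
    def _p(s):
        if isinstance(s, str):
            s = scheme_presets()[s]
        if s.kind == "precursor":
            return 1.0 / 6.0
        if s.kind == "uniform":
            return 1.0
        return s.p_methyl * s.probability_scale
    return _p(scheme_a) / _p(scheme_b)


@dataclass
class LabelledEnsemble:
    """Boolean 1H occupancy for n_replicas stochastic labelling replicas."""

    structure: ProteinStructure
    sites: list
    occupancy: np.ndarray  # (n_replicas, n_sites) bool
    scheme: LabellingScheme
    seed: int

    def __post_init__(self):
        if self.occupancy.shape != (self.occupancy.shape[0], len(self.sites)):
            raise ValueError("occupancy shape mismatch")

    @property
    def n_replicas(self) -> int:
        return self.occupancy.shape[0]


def assign_isotopomers(
    structure: ProteinStructure,
    scheme: LabellingScheme,
    n_replicas: int,
    seed: int = 0,
) -> LabelledEnsemble:
    """Draw n_replicas stochastic 1H/2H assignments for all proton sites."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    sites = structure.proton_sites()
    if not sites:
        raise ValueError("structure has no classified proton sites")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    if scheme.kind in ("random", "uniform"):
        p = np.array([scheme.site_probability(s) for s in sites])
        occ = rng.random((n_replicas, n_sites)) < p[None, :]
    else:
        occ = np.zeros((n_replicas, n_sites), dtype=bool)
        exch = np.array([s.site_class == "exchangeable" for s in sites])
        if scheme.exchangeable_h_fraction > 0:
            occ[:, exch] = (
                rng.random((n_replicas, int(exch.sum())))
                < scheme.exchangeable_h_fraction
            )
        # group Leu/Val methyl sites per residue
        residues: dict[tuple, dict[str, list[int]]] = {}
        for i, s in enumerate(sites):
            if s.site_class == "methyl" and s.residue_type in ("LEU", "VAL"):
                key = (s.chain, s.residue_index)
                residues.setdefault(key, {}).setdefault(s.methyl_group_id, []).append(i)
        for key, groups in sorted(residues.items()):
            if len(groups) != 2 or any(len(v) != 3 for v in groups.values()):
                warnings.warn(
                    f"residue {key} lacks two complete methyl groups; skipped"
                )
                continue
            group_sites = np.array([sorted(v) for _, v in sorted(groups.items())])
            which_methyl = rng.integers(0, 2, n_replicas)
            which_pos = rng.integers(0, 3, n_replicas)
            chosen = group_sites[which_methyl, which_pos]
            occ[np.arange(n_replicas), chosen] = True
    return LabelledEnsemble(structure, sites, occ, scheme, seed)


def _element_counts(structure: ProteinStructure) -> dict[str, int]:
    counts: dict[str, int] = {}
    for el in structure.elements:
        counts[el] = counts.get(el, 0) + 1
    return counts


def _validate_residues(structure: ProteinStructure) -> None:
    for ch, rs in structure.residue_keys():
        idx = structure._residue_atoms(ch, rs)
        rname = structure.res_names[idx[0]]
        if rname not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue type {rname!r} for mass model")
        n_h = sum(1 for i in idx if structure.elements[i] in ("H", "D"))
        if n_h != RESIDUE_FORMULAS[rname][0][1]:
            warnings.warn(
                f"{rname}{rs}: {n_h} explicit H differ from the formula count "
                f"{RESIDUE_FORMULAS[rname][0][1]}; mass uses the explicit sites"
            )


def theoretical_mass(
    structure: ProteinStructure,
    scheme: LabellingScheme,
    n_replicas: int = 1000,
    seed: int = 0,
    ensemble: LabelledEnsemble | None = None,
) -> tuple[float, float]:
    """Ensemble mean and sd of the molecular mass under a labelling scheme.

    Carbons are 13C with residual 12C (``c12_fraction``); occupied H sites
    are 1H; unoccupied non-exchangeable sites are 2H except for a residual
    protonation floor; unoccupied exchangeable sites are 2H (D2O buffer).
    One water (exchangeable H) is added per chain for the termini. N, O and
    S use average atomic masses.
    """
    _validate_residues(structure)
    if ensemble is None:
        ensemble = assign_isotopomers(structure, scheme, n_replicas, seed)
    rng = np.random.default_rng(seed + 1)
    counts = _element_counts(structure)
    n_c = counts.get("C", 0)
    base = counts.get("N", 0) * MASS_N + counts.get("O", 0) * MASS_O \
        + counts.get("S", 0) * MASS_S
    n_chains = len(set(structure.chains))
    f_ex = scheme.exchangeable_h_fraction
    base += n_chains * (MASS_O + 2.0 * (f_ex * MASS_1H + (1 - f_ex) * MASS_2H))

    occ = ensemble.occupancy
    n_rep = occ.shape[0]
    exch = np.array([s.site_class == "exchangeable" for s in ensemble.sites])
    # residual protonation: unoccupied non-exchangeable sites may still be 1H
    resid = (~occ) & (~exch)[None, :] & (
        rng.random(occ.shape) < scheme.residual_protonation
    )
    is_h = occ | resid
    n_h1 = is_h.sum(axis=1)
    n_h2 = occ.shape[1] - n_h1
    # carbon isotope mixture, sampled per replica
    n_c12 = rng.binomial(n_c, scheme.c12_fraction, size=n_rep)
    mass = (
        base
        + n_h1 * MASS_1H
        + n_h2 * MASS_2H
        + n_c12 * MASS_12C
        + (n_c - n_c12) * MASS_13C
    )
    sd = float(np.std(mass, ddof=1)) if n_rep > 1 else 0.0
    return float(np.mean(mass)), sd
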