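"""Protein structure container, PDB I/O and proton-site classification.

Hydrogen sites are classified for the labelling simulation:

* ``methyl``       -- H on a methyl carbon (Ala CB, Ile CG2/CD1, Leu CD1/CD2,
                      Met CE, Thr CG2, Val CG1/CG2)
* ``exchangeable`` -- H bound to N, O or S (amides, hydroxyls, thiols)
* ``aromatic``     -- H on an aromatic ring carbon (Phe, Tyr, Trp, His)
* ``aliphatic``    -- every other carbon-bound H

The bonded heavy atom is taken as the nearest heavy atom within the same
residue. Prochirality of the two Val/Leu methyls is assigned geometrically
from the heavy-atom coordinates (CIP-style: promote one methyl above the
other, lowest priority to the attached H).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import CH_BUILD_LENGTH, methyl_hydrogens

__all__ = ["ProtonSite", "ProteinStructure", "read_structure"]

METHYL_CARBONS = {
    ("ALA", "CB"), ("ILE", "CG2"), ("ILE", "CD1"), ("LEU", "CD1"),
    ("LEU", "CD2"), ("MET", "CE"), ("THR", "CG2"), ("VAL", "CG1"), ("VAL", "CG2"),
}

_AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2", "NE1"},
    "HIS": {"CG", "CD2", "CE1", "ND1", "NE2"},
}

# (center, reference substituent) for geometric prochirality of methyl pairs
_PROCHIRAL = {
    "VAL": ("CB", "CA", ("CG1", "CG2")),
    "LEU": ("CG", "CB", ("CD1", "CD2")),
}


@dataclass(frozen=True)
class ProtonSite:
    """One hydrogen position eligible for 1H/2H assignment."""

    atom_index: int
    atom_name: str
    residue_index: int
    residue_type: str
    chain: str
    coords: tuple
    site_class: str  # methyl | aliphatic | exchangeable | aromatic
    methyl_group_id: str | None = None
    methyl_position: int | None = None
    prochirality: str = "none"

    @property
    def site_id(self) -> str:
        return f"{self.chain}:{self.residue_type}{self.residue_index}:{self.atom_name}"


@dataclass
class ProteinStructure:
    """Flat atom table with cached classified proton sites."""

    names: list
    elements: list
    res_names: list
    res_seqs: np.ndarray
    chains: list
    coords: np.ndarray
    _sites: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_seqs = np.asarray(self.res_seqs, dtype=int)
        n = len(self.names)
        if not (len(self.elements) == len(self.res_names) == self.res_seqs.size
                == len(self.chains) == self.coords.shape[0] == n):
            raise ValueError("inconsistent atom table lengths")

    def __len__(self) -> int:
        return len(self.names)

    # -- residue bookkeeping ------------------------------------------------
    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain, residue_index) pairs in order of first appearance."""
        seen, keys = set(), []
        for ch, rs in zip(self.chains, self.res_seqs):
            k = (ch, int(rs))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    def _residue_atoms(self, chain: str, res_seq: int) -> np.ndarray:
        mask = (np.array(self.chains) == chain) & (self.res_seqs == res_seq)
        return np.flatnonzero(mask)

    # -- proton sites -------------------------------------------------------
    def proton_sites(self) -> list[ProtonSite]:
        if not self._sites:
            self._sites = _classify_protons(self)
        return self._sites

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "ProteinStructure":
        names, elements, res_names, res_seqs, chains, coords = [], [], [], [], [], []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    res_names.append(res.name)
                    res_seqs.append(res.seqid.num)
                    chains.append(chain.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not names:
            raise ValueError("structure contains no ATOM records")
        return cls(names, elements, res_names, np.array(res_seqs), chains,
                   np.array(coords))

    def to_gemmi(self, name: str = "methylrap") -> gemmi.Structure:
        # gemmi add_* methods copy their argument: build bottom-up
        by_chain: dict[str, dict[tuple, list[int]]] = {}
        for i in range(len(self)):
            rkey = (int(self.res_seqs[i]), self.res_names[i])
            by_chain.setdefault(self.chains[i], {}).setdefault(rkey, []).append(i)
        st = gemmi.Structure()
        st.name = name
        model = gemmi.Model("1")
        for ch_name, residues in by_chain.items():
            chain = gemmi.Chain(ch_name)
            for (seq, rname), idxs in residues.items():
                res = gemmi.Residue()
                res.name = rname
                res.seqid = gemmi.SeqId(seq, " ")
                for i in idxs:
                    atom = gemmi.Atom()
                    atom.name = self.names[i]
                    atom.element = gemmi.Element(self.elements[i])
                    atom.pos = gemmi.Position(*self.coords[i])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        return st

    def write_pdb(self, path: str | Path) -> None:
        self.to_gemmi().write_pdb(str(path))

    # -- hydrogen building --------------------------------------------------
    def build_missing_methyl_hydrogens(self, bond: float = CH_BUILD_LENGTH) -> int:
        """Construct ideal sp3 H for methyl carbons lacking explicit H.

        Returns the number of hydrogens added; invalidates the site cache.
        """
        added_names, added_coords, added_meta = [], [], []
        for ch, rs in self.residue_keys():
            idx = self._residue_atoms(ch, rs)
            rname = self.res_names[idx[0]]
            name_to_i = {self.names[i]: i for i in idx}
            for res_t, carbon in METHYL_CARBONS:
                if res_t != rname or carbon not in name_to_i:
                    continue
                ci = name_to_i[carbon]
                has_h = any(
                    self.elements[i] in ("H", "D")
                    and np.linalg.norm(self.coords[i] - self.coords[ci]) < 1.3
                    for i in idx
                )
                if has_h:
                    continue
                parent = min(
                    (i for i in idx if i != ci and self.elements[i] not in ("H", "D")),
                    key=lambda i: np.linalg.norm(self.coords[i] - self.coords[ci]),
                )
                hpos = methyl_hydrogens(self.coords[ci], self.coords[parent], bond=bond)
                base = "H" + carbon[1:]
                for k in range(3):
                    added_names.append(f"{base}{k + 1}")
                    added_coords.append(hpos[k])
                    added_meta.append((rname, rs, ch))
        for nm, xyz, (rn, rs, ch) in zip(added_names, added_coords, added_meta):
            self.names.append(nm)
            self.elements.append("H")
            self.res_names.append(rn)
            self.res_seqs = np.append(self.res_seqs, rs)
            self.chains.append(ch)
            self.coords = np.vstack([self.coords, xyz])
        self._sites = []
        return len(added_names)


def read_structure(path: str | Path, build_missing_h: bool = False) -> ProteinStructure:
    """Read a PDB file and classify its hydrogen sites."""
    st = gemmi.read_structure(str(path))
    ps = ProteinStructure.from_gemmi(st)
    if build_missing_h:
        ps.build_missing_methyl_hydrogens()
    ps.proton_sites()
    return ps


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _prochirality_labels(struct: ProteinStructure, idx: np.ndarray, rname: str) -> dict:
    """Map methyl carbon name -> proR/proS for Val/Leu, geometrically."""
    if rname not in _PROCHIRAL:
        return {}
    center_n, ref_n, (m1, m2) = _PROCHIRAL[rname]
    names = {struct.names[i]: i for i in idx}
    if not {center_n, ref_n, m1, m2} <= names.keys():
        return {}
    c = struct.coords[names[center_n]]
    va = struct.coords[names[ref_n]] - c
    v1 = struct.coords[names[m1]] - c
    v2 = struct.coords[names[m2]] - c
    # promote m1 over m2 (ref stays highest, attached H lowest):
    # R configuration <=> a -> m1 -> m2 clockwise viewed with H pointing away
    # <=> negative triple product va . (v1 x v2)
    trip = float(np.dot(va, np.cross(v1, v2)))
    if trip < 0:
        return {m1: "proR", m2: "proS"}
    return {m1: "proS", m2: "proR"}


def _classify_protons(struct: ProteinStructure) -> list[ProtonSite]:
    sites: list[ProtonSite] = []
    coords = struct.coords
    for ch, rs in struct.residue_keys():
        idx = struct._residue_atoms(ch, rs)
        rname = struct.res_names[idx[0]]
        heavy = [i for i in idx if struct.elements[i] not in ("H", "D")]
        prochi = _prochirality_labels(struct, idx, rname)
        methyl_counters: dict[str, int] = {}
        for i in idx:
            if struct.elements[i] not in ("H", "D"):
                continue
            if not heavy:
                warnings.warn(f"residue {rname}{rs} has no heavy atoms; H skipped")
                continue
            d = np.linalg.norm(coords[heavy] - coords[i], axis=1)
            parent = heavy[int(np.argmin(d))]
            if d.min() > 2.0:
                warnings.warn(
                    f"H {struct.names[i]} in {rname}{rs} has no bonded heavy atom "
                    "within 2 A; classified aliphatic"
                )
            p_el = struct.elements[parent]
            p_name = struct.names[parent]
            group_id = None
            position = None
            prochirality = "none"
            if p_el in ("N", "O", "S"):
                s_class = "exchangeable"
            elif (rname, p_name) in METHYL_CARBONS:
                s_class = "methyl"
                group_id = f"{ch}:{rs}:{p_name}"
                methyl_counters[p_name] = methyl_counters.get(p_name, 0) + 1
                position = methyl_counters[p_name]
                prochirality = prochi.get(p_name, "none")
            elif p_name in _AROMATIC_CARBONS.get(rname, set()):
                s_class = "aromatic"
            else:
                s_class = "aliphatic"
            sites.append(
                ProtonSite(
                    atom_index=int(i),
                    atom_name=struct.names[i],
                    residue_index=int(rs),
                    residue_type=rname,
                    chain=ch,
                    coords=tuple(coords[i]),
                    site_class=s_class,
                    methyl_group_id=group_id,
                    methyl_position=position,
                    prochirality=prochirality,
                )
            )
    return sites
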