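"""Chlorophyll Mg coordination, hydration classes, and hydrogen bonds.

The chlorophyll Mg is four-coordinated by the tetrapyrrole nitrogens; any
additional N/O/S heavy atom of *another* residue within ``cutoff``
(default 2.9 Å — axial Mg-O/N bonds are 2.0-2.6 Å, and 2.9 absorbs
coordinate error at ~2.3 Å resolution) counts as an axial ligand.  Sites
are classed anhydrous / mono-hydrated / di-hydrated by their number of
axial waters.

Hydrogen bonds use a hydrogen-free geometric criterion (deposited
coordinates carry no hydrogens): donor-acceptor heavy-atom distance <=
``d_max`` and antecedent-donor-acceptor angle >= ``angle_min``; waters are
exempt from the angle term because their antecedent is unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import components as comp
from .model import Atom, Residue, StructureModel, select_residues

ANHYDROUS = "anhydrous"
MONO_HYDRATED = "mono_hydrated"
DI_HYDRATED = "di_hydrated"

#: tetrapyrrole nitrogens — part of the ring, never axial ligands
RING_NITROGENS = frozenset({"NA", "NB", "NC", "ND"})

LIGAND_ELEMENTS = frozenset({"N", "O", "S"})

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: hydroxyl oxygens that can donate a hydrogen bond
HYDROXYL_OXYGENS = frozenset({"OG", "OG1", "OH"})

HIS_RING_NITROGENS = frozenset({"ND1", "NE2"})


@dataclass
class AxialLigand:
    category: str              # protein_sidechain/protein_backbone/water/lipid/pigment/other
    residue: Residue
    atom_name: str
    distance: float


@dataclass
class CoordinationRecord:
    site: tuple[str, int, str]
    axial_ligands: list[AxialLigand] = field(default_factory=list)

    @property
    def coordination_number(self) -> int:
        return 4 + len(self.axial_ligands)

    @property
    def n_waters(self) -> int:
        return sum(1 for lig in self.axial_ligands if lig.category == "water")

    @property
    def hydration_class(self) -> str:
        n = self.n_waters
        if n == 0:
            return ANHYDROUS
        if n == 1:
            return MONO_HYDRATED
        return DI_HYDRATED


@dataclass
class HBond:
    donor_residue: Residue
    donor_atom: str
    acceptor_residue: Residue
    acceptor_atom: str
    distance: float
    donor_angle: Optional[float]   # degrees; None for water donors
    ambiguous_roles: bool = False  # O-O pair where either side could donate


@dataclass
class HydrationStats:
    n_chl_a: int
    n_chl_b: int
    frac_water_coordinated_a: float
    frac_water_coordinated_b: float
    ratio_b_over_a: Optional[float]   # None when undefined
    n_di_hydrated: int
    records: list[CoordinationRecord] = field(default_factory=list)


def _ligand_category(residue: Residue, atom_name: str) -> str:
    if residue.category == comp.WATER:
        return "water"
    if residue.category == comp.PROTEIN:
        return ("protein_backbone" if atom_name in BACKBONE_ATOMS
                else "protein_sidechain")
    if residue.category == comp.LIPID:
        return "lipid"
    if residue.category in comp.PIGMENT_CATEGORIES:
        return "pigment"
    return "other"


class _LigandIndex:
    """KD-tree over all candidate ligand atoms (N/O/S, heavy) of a model."""

    def __init__(self, model: StructureModel):
        self.entries: list[tuple[Residue, Atom]] = [
            (r, a) for r, a in model.atoms()
            if a.is_heavy and a.element.upper() in LIGAND_ELEMENTS]
        self.tree = (cKDTree(np.vstack([a.pos for _, a in self.entries]))
                     if self.entries else None)

    def near(self, point: np.ndarray, cutoff: float):
        if self.tree is None:
            return
        for idx in self.tree.query_ball_point(point, cutoff):
            yield self.entries[idx]


def axial_ligands(model: StructureModel, site: tuple[str, int, str] | Residue,
                  cutoff: float = 2.9,
                  _index: Optional[_LigandIndex] = None) -> CoordinationRecord:
    """Axial-ligand record for one chlorophyll site.

    ``site`` is a residue or (chain_id, auth_seq_id, comp_code) tuple.
    """
    if isinstance(site, Residue):
        res = site
    else:
        res = model.find_residue(site[0], site[1])
        if res.comp_code != site[2]:
            raise TypeError(f"site {site} is {res.comp_code}, not {site[2]}")
    if not res.is_chlorophyll:
        raise TypeError(f"site {res.site} is {res.category}, not a chlorophyll")
    mg = res.mg
    if mg is None:
        raise ValueError(f"chlorophyll {res.site} has no Mg atom")
    index = _index or _LigandIndex(model)
    ligands = []
    for other, atom in index.near(mg.pos, cutoff):
        if other is res:
            continue
        d = float(np.linalg.norm(atom.pos - mg.pos))
        if d <= cutoff:
            ligands.append(AxialLigand(_ligand_category(other, atom.name),
                                       other, atom.name, d))
    ligands.sort(key=lambda lig: lig.distance)
    return CoordinationRecord((res.chain_id, res.auth_seq_id, res.comp_code),
                              ligands)


def hydration_census(model: StructureModel,
                     cutoff: float = 2.9) -> HydrationStats:
    """Water-coordination statistics per chlorophyll type.

    Reports, for Chl a and Chl b separately, the fraction of sites with at
    least one axial water, the Chl b : Chl a ratio of these fractions
    (``None`` when the Chl a fraction is zero or a type is absent), and the
    number of di-hydrated sites.
    """
    index = _LigandIndex(model)
    records = [axial_ligands(model, r, cutoff, _index=index)
               for r in model.chlorophylls()]
    by_type = {comp.CHL_A: [], comp.CHL_B: []}
    for res, rec in zip(model.chlorophylls(), records):
        by_type[res.category].append(rec)
    n_a, n_b = len(by_type[comp.CHL_A]), len(by_type[comp.CHL_B])
    frac_a = (sum(r.n_waters > 0 for r in by_type[comp.CHL_A]) / n_a
              if n_a else 0.0)
    frac_b = (sum(r.n_waters > 0 for r in by_type[comp.CHL_B]) / n_b
              if n_b else 0.0)
    ratio = frac_b / frac_a if (n_a and n_b and frac_a > 0) else None
    return HydrationStats(n_a, n_b, frac_a, frac_b, ratio,
                          sum(r.hydration_class == DI_HYDRATED
                              for r in records),
                          records)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donors(residues: list[Residue]):
    for r in residues:
        if r.category == comp.WATER:
            for a in r.atoms:
                if a.element.upper() == "O":
                    yield r, a, True
            continue
        for a in r.atoms:
            if not a.is_heavy:
                continue
            el = a.element.upper()
            if el == "N" or (el == "O" and a.name in HYDROXYL_OXYGENS):
                yield r, a, False


def _acceptors(residues: list[Residue]):
    for r in residues:
        for a in r.atoms:
            if not a.is_heavy:
                continue
            el = a.element.upper()
            if el == "O":
                yield r, a
            elif (el == "N" and r.comp_code.upper() == "HIS"
                  and a.name in HIS_RING_NITROGENS):
                yield r, a


def _antecedent(residue: Residue, donor: Atom) -> Optional[np.ndarray]:
    """Nearest bonded heavy atom of the donor within its own residue."""
    best, best_d = None, 2.0
    for a in residue.atoms:
        if a is donor or not a.is_heavy:
            continue
        d = float(np.linalg.norm(a.pos - donor.pos))
        if d < best_d:
            best, best_d = a.pos, d
    return best


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _can_donate(residue: Residue, atom: Atom) -> bool:
    el = atom.element.upper()
    return (residue.category == comp.WATER or el == "N"
            or (el == "O" and atom.name in HYDROXYL_OXYGENS))


def find_hbonds(model: StructureModel, group_a, group_b,
                d_max: float = 3.5, angle_min: float = 90.0,
                allow_intra_residue: bool = False) -> list[HBond]:
    """Geometric hydrogen bonds between two residue groups.

    Groups are selection-expression strings or lists of residues.  Each bond
    is reported once; O-O pairs where either oxygen could donate carry the
    ``ambiguous_roles`` flag.
    """
    res_a = (select_residues(model, group_a) if isinstance(group_a, str)
             else list(group_a))
    res_b = (select_residues(model, group_b) if isinstance(group_b, str)
             else list(group_b))
    bonds: list[HBond] = []
    seen: set[tuple[int, int]] = set()

    def trial(dr: Residue, da: Atom, is_water: bool, ar: Residue, aa: Atom,
              swapped: bool):
        if dr is ar and not allow_intra_residue:
            return
        d = float(np.linalg.norm(da.pos - aa.pos))
        if d > d_max or d < 1e-6:
            return
        key = tuple(sorted((id(da), id(aa))))
        if key in seen:
            return
        angle = None
        if not is_water:
            ant = _antecedent(dr, da)
            if ant is not None:
                angle = _angle_deg(ant, da.pos, aa.pos)
                if angle < angle_min:
                    return
        seen.add(key)
        ambiguous = (da.element.upper() == "O" and aa.element.upper() == "O"
                     and _can_donate(ar, aa))
        bonds.append(HBond(dr, da.name, ar, aa.name, d, angle, ambiguous))

    acceptors_b = list(_acceptors(res_b))
    tree_b = (cKDTree(np.vstack([a.pos for _, a in acceptors_b]))
              if acceptors_b else None)
    for dr, da, is_water in _donors(res_a):
        if tree_b is None:
            break
        for idx in tree_b.query_ball_point(da.pos, d_max):
            ar, aa = acceptors_b[idx]
            trial(dr, da, is_water, ar, aa, False)
    acceptors_a = list(_acceptors(res_a))
    tree_a = (cKDTree(np.vstack([a.pos for _, a in acceptors_a]))
              if acceptors_a else None)
    for dr, da, is_water in _donors(res_b):
        if tree_a is None:
            break
        for idx in tree_a.query_ball_point(da.pos, d_max):
            ar, aa = acceptors_a[idx]
            trial(dr, da, is_water, ar, aa, True)
    bonds.sort(key=lambda b: b.distance)
    return bonds


def write_coordination_tsv(records: list[CoordinationRecord],
                           path: str | Path) -> None:
    lines = ["chain_id\tauth_seq_id\tcomp_code\tcoordination_number\t"
             "hydration_class\tligands"]
    for rec in records:
        ligs = ";".join(f"{l.category}:{l.residue.comp_code}"
                        f"{l.residue.auth_seq_id}/{l.atom_name}"
                        f"@{l.distance:.2f}" for l in rec.axial_ligands)
        lines.append(f"{rec.site[0]}\t{rec.site[1]}\t{rec.site[2]}\t"
                     f"{rec.coordination_number}\t{rec.hydration_class}\t"
                     f"{ligs or '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hbond_tsv(bonds: list[HBond], path: str | Path) -> None:
    lines = ["donor\tdonor_atom\tacceptor\tacceptor_atom\tdistance\t"
             "donor_angle\tambiguous"]
    for b in bonds:
        dr, ar = b.donor_residue, b.acceptor_residue
        ang = f"{b.donor_angle:.1f}" if b.donor_angle is not None else "-"
        lines.append(f"{dr.chain_id}/{dr.comp_code}{dr.auth_seq_id}\t"
                     f"{b.donor_atom}\t"
                     f"{ar.chain_id}/{ar.comp_code}{ar.auth_seq_id}\t"
                     f"{b.acceptor_atom}\t{b.distance:.3f}\t{ang}\t"
                     f"{int(b.ambiguous_roles)}")
    Path(path).write_text("\n".join(lines) + "\n")
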