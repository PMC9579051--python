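"""Contact analysis between two chain groups.

Three layers of description: residue-residue heavy-atom contacts (<= 4.0 Å,
a standard van der Waals contact distance), geometric hydrogen bonds
(delegated to :mod:`photosys.coordination`), and cofactor bridges —
non-protein residues (lipids, pigments) that touch both groups and thereby
glue them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import components as comp
from .coordination import HBond, find_hbonds
from .model import Residue, StructureModel, select_residues


@dataclass
class ContactRecord:
    residue_a: Residue
    residue_b: Residue
    min_distance: float
    atom_a: str
    atom_b: str


@dataclass
class CofactorBridge:
    bridge: Residue
    contacts_group1: list[tuple[Residue, float]]
    contacts_group2: list[tuple[Residue, float]]
    own_group: Optional[int]   # 1, 2 or None (unassigned chain)

    @property
    def total_contacts(self) -> int:
        return len(self.contacts_group1) + len(self.contacts_group2)


@dataclass
class InterfaceReport:
    contacts: list[ContactRecord] = field(default_factory=list)
    hbonds: list[HBond] = field(default_factory=list)
    bridges: list[CofactorBridge] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        return {"n_contacts": len(self.contacts),
                "n_hbonds": len(self.hbonds),
                "n_bridges": len(self.bridges)}


def _resolve(model: StructureModel, group) -> list[Residue]:
    if isinstance(group, str):
        return select_residues(model, group)
    return list(group)


def _atom_entries(residues: list[Residue]):
    return [(r, a) for r in residues for a in r.atoms if a.is_heavy]


def _min_dist_pairs(res_a: list[Residue], res_b: list[Residue],
                    cutoff: float) -> list[ContactRecord]:
    ents_a, ents_b = _atom_entries(res_a), _atom_entries(res_b)
    if not ents_a or not ents_b:
        return []
    tree_b = cKDTree(np.vstack([a.pos for _, a in ents_b]))
    best: dict[tuple, ContactRecord] = {}
    for ra, aa in ents_a:
        for idx in tree_b.query_ball_point(aa.pos, cutoff):
            rb, ab = ents_b[idx]
            d = float(np.linalg.norm(aa.pos - ab.pos))
            if d > cutoff:
                continue
            key = (ra.key, rb.key)
            if key not in best or d < best[key].min_distance:
                best[key] = ContactRecord(ra, rb, d, aa.name, ab.name)
    return sorted(best.values(),
                  key=lambda c: (c.residue_a.key, c.residue_b.key))


def interface_contacts(model: StructureModel, group1, group2,
                       cutoff: float = 4.0, hbond_dmax: float = 3.5,
                       hbond_angle_min: float = 90.0,
                       bridge_cutoff: Optional[float] = None
                       ) -> InterfaceReport:
    """Full interface report between two disjoint residue groups."""
    res1, res2 = _resolve(model, group1), _resolve(model, group2)
    keys1 = {r.key for r in res1}
    overlap = [r for r in res2 if r.key in keys1]
    if overlap:
        raise ValueError(
            f"groups overlap at {len(overlap)} residues, "
            f"e.g. {overlap[0].site}")
    report = InterfaceReport()
    report.contacts = _min_dist_pairs(res1, res2, cutoff)
    report.hbonds = find_hbonds(model, res1, res2, hbond_dmax,
                                hbond_angle_min)
    report.bridges = cofactor_bridges(model, res1, res2,
                                      bridge_cutoff or cutoff)
    return report


def cofactor_bridges(model: StructureModel, group1, group2,
                     cutoff: float = 4.0) -> list[CofactorBridge]:
    """Non-protein residues in contact with both groups.

    A cofactor belonging to one group's chains may still bridge (its own
    contacts within that group are counted toward it); cofactors on
    unassigned chains are eligible as free bridges.  Sorted by total
    contact count, largest first.
    """
    res1, res2 = _resolve(model, group1), _resolve(model, group2)
    keys1, keys2 = {r.key for r in res1}, {r.key for r in res2}
    candidates = [r for r in model.residues()
                  if r.category not in (comp.PROTEIN, comp.WATER)]
    prot1 = [r for r in res1 if r.category != comp.WATER]
    prot2 = [r for r in res2 if r.category != comp.WATER]
    bridges = []
    for cand in candidates:
        own = 1 if cand.key in keys1 else 2 if cand.key in keys2 else None
        c1 = _residue_contacts(cand, [r for r in prot1 if r is not cand],
                               cutoff)
        c2 = _residue_contacts(cand, [r for r in prot2 if r is not cand],
                               cutoff)
        if c1 and c2:
            bridges.append(CofactorBridge(cand, c1, c2, own))
    bridges.sort(key=lambda b: -b.total_contacts)
    return bridges


def _residue_contacts(res: Residue, others: list[Residue],
                      cutoff: float) -> list[tuple[Residue, float]]:
    pts = res.coords()
    if pts.size == 0:
        return []
    tree = cKDTree(pts)
    out = []
    for other in others:
        opts = other.coords()
        if opts.size == 0:
            continue
        d = tree.query(opts, k=1)[0].min()
        if d <= cutoff:
            out.append((other, float(d)))
    out.sort(key=lambda t: t[1])
    return out


def residue_window_composition(model: StructureModel, chain_id: str,
                               start: int, end: int,
                               target_codes) -> tuple[int, list[int]]:
    """Count residues with the given component code(s) in an inclusive
    author-numbering window; returns (count, sorted positions)."""
    if start > end:
        raise ValueError(f"window start {start} > end {end}")
    chain = model.chain(chain_id)
    if chain is None:
        raise KeyError(f"no chain {chain_id!r}")
    if isinstance(target_codes, str):
        target_codes = [target_codes]
    codes = {c.upper() for c in target_codes}
    positions = sorted(r.auth_seq_id for r in chain.residues
                       if start <= r.auth_seq_id <= end
                       and r.comp_code.upper() in codes)
    return len(positions), positions


def write_interface_tsv(report: InterfaceReport, path: str | Path) -> None:
    lines = ["type\tpartner_a\tpartner_b\tdistance\tdetail"]
    for c in report.contacts:
        ra, rb = c.residue_a, c.residue_b
        lines.append(f"contact\t{ra.chain_id}/{ra.comp_code}{ra.auth_seq_id}"
                     f"\t{rb.chain_id}/{rb.comp_code}{rb.auth_seq_id}"
                     f"\t{c.min_distance:.3f}\t{c.atom_a}-{c.atom_b}")
    for b in report.hbonds:
        dr, ar = b.donor_residue, b.acceptor_residue
        lines.append(f"hbond\t{dr.chain_id}/{dr.comp_code}{dr.auth_seq_id}"
                     f"\t{ar.chain_id}/{ar.comp_code}{ar.auth_seq_id}"
                     f"\t{b.distance:.3f}\t{b.donor_atom}-{b.acceptor_atom}")
    for br in report.bridges:
        r = br.bridge
        parts = "+".join(f"{o.comp_code}{o.auth_seq_id}"
                         for o, _ in (br.contacts_group1[:1]
                                      + br.contacts_group2[:1]))
        lines.append(f"bridge\t{r.chain_id}/{r.comp_code}{r.auth_seq_id}"
                     f"\t{parts}\t-\town_group={br.own_group}")
    Path(path).write_text("\n".join(lines) + "\n")
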