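"""Rigid least-squares superposition (Kabsch) and steric-clash analysis.

``kabsch_superpose`` solves the closed-form SVD problem on paired CA
atoms, with the reflection branch corrected so the rotation is proper.
``detect_clashes`` flags atom pairs closer than the sum of their van der
Waals radii minus a tolerance (0.4 Å default), the usual criterion for
"would clash" statements about superposed models.  ``overlap_analysis``
combines the two: anchor one complex onto part of another, then ask which
probe chains would collide with which host chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel

#: van der Waals radii (Å) by element; unknown elements fall back to carbon
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "MG": 1.73,
             "FE": 1.56}
VDW_FALLBACK = 1.70


class DegeneratePairingError(ValueError):
    pass


@dataclass
class Superposition:
    rotation: np.ndarray       # 3x3, proper orthonormal
    translation: np.ndarray    # 3-vector
    rmsd: float
    n_pairs: int
    pairing: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.rotation.T + self.translation

    def transform_model(self, model: StructureModel,
                        chain_ids: Optional[set[str]] = None
                        ) -> StructureModel:
        return model.transformed(self.rotation, self.translation, chain_ids)

    def to_matrix_file(self, path: str | Path) -> None:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        np.savetxt(path, m, fmt="%.6f")


@dataclass
class Clash:
    ref_a: str                 # "chain/COMPseq/atom"
    ref_b: str
    chain_a: str
    chain_b: str
    distance: float
    overlap: float             # (rA + rB - tolerance) - distance, > 0


@dataclass
class ClashReport:
    clashes: list[Clash] = field(default_factory=list)
    tolerance: float = 0.4

    def __len__(self) -> int:
        return len(self.clashes)

    def per_chain_pair(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for c in self.clashes:
            key = (c.chain_a, c.chain_b)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def verdicts(self, min_clashes: int = 10) -> dict[tuple[str, str], bool]:
        """Chain-pair 'would clash' verdicts: at least ``min_clashes``
        clashing atom pairs separates genuine overlap from grazing
        contact."""
        return {k: v >= min_clashes for k, v in self.per_chain_pair().items()}

    def to_tsv(self, path: str | Path) -> None:
        lines = ["atom_a\tatom_b\tdistance\toverlap"]
        for c in self.clashes:
            lines.append(f"{c.ref_a}\t{c.ref_b}\t{c.distance:.3f}\t"
                         f"{c.overlap:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form least-squares rotation+translation mapping ``mobile``
    onto ``target`` (paired rows).  Returns (R, t, rmsd) with det(R)=+1."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n,3) coordinate arrays required")
    n = len(P)
    if n < 3:
        raise DegeneratePairingError(f"need >= 3 pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of centered mobile set
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegeneratePairingError("paired atoms are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def _paired_ca(mobile: StructureModel, target: StructureModel,
               pairing: Sequence[tuple[str, str]]
               ) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates matched by auth_seq_id within paired chains."""
    ps, qs = [], []
    for mob_id, tgt_id in pairing:
        mch, tch = mobile.chain(mob_id), target.chain(tgt_id)
        if mch is None or tch is None:
            raise KeyError(f"pairing chain missing: {mob_id!r}/{tgt_id!r}")
        tgt_by_seq = {(r.auth_seq_id, r.icode): r for r in tch.residues}
        for r in mch.residues:
            other = tgt_by_seq.get((r.auth_seq_id, r.icode))
            if other is None:
                continue
            ca_m, ca_t = r.atom("CA"), other.atom("CA")
            if ca_m is not None and ca_t is not None:
                ps.append(ca_m.pos)
                qs.append(ca_t.pos)
    if not ps:
        raise DegeneratePairingError("pairing produced no CA pairs")
    return np.vstack(ps), np.vstack(qs)


def kabsch_superpose(mobile: StructureModel, target: StructureModel,
                     pairing: Sequence[tuple[str, str]]) -> Superposition:
    """Superpose ``mobile`` onto ``target`` over CA atoms of paired chains
    (matched by author residue numbering)."""
    P, Q = _paired_ca(mobile, target, pairing)
    R, t, rmsd = kabsch(P, Q)
    return Superposition(R, t, rmsd, len(P),
                         ";".join(f"{a}->{b}" for a, b in pairing))


def _atom_entries(model: StructureModel, chain_ids=None):
    out = []
    for chain in model.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        for r in chain.residues:
            for a in r.atoms:
                if a.is_heavy:
                    out.append((f"{chain.chain_id}/{r.comp_code}"
                                f"{r.auth_seq_id}/{a.name}",
                                chain.chain_id, a.element.upper(), a.pos))
    return out


def detect_clashes(atoms_a, atoms_b, tolerance: float = 0.4) -> ClashReport:
    """Steric overlaps between two heavy-atom sets.

    Each input is either a StructureModel or a (model, chain_ids) tuple.
    Clash iff ``distance < r_A + r_B - tolerance`` (strict inequality).
    """
    ents_a = (_atom_entries(*atoms_a) if isinstance(atoms_a, tuple)
              else _atom_entries(atoms_a))
    ents_b = (_atom_entries(*atoms_b) if isinstance(atoms_b, tuple)
              else _atom_entries(atoms_b))
    report = ClashReport(tolerance=tolerance)
    if not ents_a or not ents_b:
        return report
    max_r = max(VDW_RADII.values())
    reach = 2 * max_r - tolerance
    tree_b = cKDTree(np.vstack([e[3] for e in ents_b]))
    for ref_a, chain_a, el_a, pos_a in ents_a:
        ra = VDW_RADII.get(el_a, VDW_FALLBACK)
        for idx in tree_b.query_ball_point(pos_a, reach):
            ref_b, chain_b, el_b, pos_b = ents_b[idx]
            rb = VDW_RADII.get(el_b, VDW_FALLBACK)
            limit = ra + rb - tolerance
            d = float(np.linalg.norm(pos_a - pos_b))
            if d < limit:
                report.clashes.append(Clash(ref_a, ref_b, chain_a, chain_b,
                                            d, limit - d))
    report.clashes.sort(key=lambda c: -c.overlap)
    return report


def overlap_analysis(reference: StructureModel, host: StructureModel,
                     anchor_pairing: Sequence[tuple[str, str]],
                     probe_chains: Sequence[str],
                     against_chains: Sequence[str],
                     tolerance: float = 0.4
                     ) -> tuple[Superposition, ClashReport]:
    """Anchor ``reference`` onto ``host`` and test which probe chains of the
    superposed reference would overlap the host's ``against_chains``."""
    sup = kabsch_superpose(reference, host, anchor_pairing)
    moved = sup.transform_model(reference)
    report = detect_clashes((moved, set(probe_chains)),
                            (host, set(against_chains)), tolerance)
    return sup, report
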