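"""In-memory structure model: chains → residues → atoms.

Author identifiers (auth chain id, auth_seq_id, insertion code) are used
throughout, because structural papers cite sites that way (G148, Q109,
CLA807).  Coordinates are in Å in the frame of the source file; nothing is
re-centered at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np

from . import components as comp


class SelectionError(ValueError):
    """Malformed selection expression; carries the offending position."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray            # shape (3,), Å
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    comp_code: str
    auth_seq_id: int
    chain_id: str
    icode: str = ""
    category: str = comp.OTHER
    carotenoid_subtype: Optional[str] = None
    atoms: list[Atom] = field(default_factory=list)

    @property
    def site(self) -> tuple[str, int, str]:
        """(chain_id, auth_seq_id, comp_code) — how sites are cited."""
        return (self.chain_id, self.auth_seq_id, self.comp_code)

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique per chain: (chain_id, auth_seq_id, icode)."""
        return (self.chain_id, self.auth_seq_id, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.vstack([a.pos for a in atoms])

    @property
    def mg(self) -> Optional[Atom]:
        for a in self.atoms:
            if a.element.upper() == "MG":
                return a
        return None

    @property
    def is_chlorophyll(self) -> bool:
        return self.category in (comp.CHL_A, comp.CHL_B)


@dataclass
class Chain:
    chain_id: str
    subunit_label: Optional[str] = None
    residues: list[Residue] = field(default_factory=list)

    @property
    def is_polymer(self) -> bool:
        return any(r.category == comp.PROTEIN for r in self.residues)

    def residue(self, auth_seq_id: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.auth_seq_id == auth_seq_id and r.icode == icode:
                return r
        return None


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    source_id: str = ""
    component_table: comp.ComponentTable = field(
        default_factory=comp.ComponentTable)

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in model")

    # -- iteration -------------------------------------------------------
    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id or c.subunit_label == chain_id:
                return c
        return None

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def heavy_coords(self) -> np.ndarray:
        pts = [a.pos for r in self.residues() for a in r.atoms if a.is_heavy]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def chlorophylls(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_chlorophyll]

    def find_residue(self, chain_id: str, auth_seq_id: int,
                     icode: str = "") -> Residue:
        ch = self.chain(chain_id)
        if ch is None:
            raise KeyError(f"no chain {chain_id!r} in model {self.source_id!r}")
        res = ch.residue(auth_seq_id, icode)
        if res is None:
            raise KeyError(f"no residue {auth_seq_id}{icode} in chain {chain_id!r}")
        return res

    def set_subunit_labels(self, labels: dict[str, str]) -> None:
        """Attach human subunit names (PsaB, Lhca9, ...) to author chain ids."""
        for c in self.chains:
            if c.chain_id in labels:
                c.subunit_label = labels[c.chain_id]

    # -- geometry --------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_ids: Optional[set[str]] = None) -> "StructureModel":
        """Copy of the model with ``x -> R x + t`` applied (optionally to a
        subset of chains)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_chains = []
        for c in self.chains:
            move = chain_ids is None or c.chain_id in chain_ids
            new_res = []
            for r in c.residues:
                atoms = [Atom(a.name, a.element,
                              R @ a.pos + t if move else a.pos.copy(),
                              a.occupancy) for a in r.atoms]
                new_res.append(Residue(r.comp_code, r.auth_seq_id, r.chain_id,
                                       r.icode, r.category,
                                       r.carotenoid_subtype, atoms))
            new_chains.append(Chain(c.chain_id, c.subunit_label, new_res))
        return StructureModel(new_chains, self.source_id, self.component_table)


def classify_components(model: StructureModel,
                        table: Optional[comp.ComponentTable] = None
                        ) -> StructureModel:
    """Assign every residue its functional category (idempotent, in place)."""
    table = table or model.component_table
    for r in model.residues():
        r.category, r.carotenoid_subtype = table.classify(r.comp_code)
    model.component_table = table
    return model


# ---------------------------------------------------------------------------
# Selection expressions
#
# Grammar:  clause ( AND clause )*
#   clause := chain=<id>[,<id>...] | range=<lo>-<hi> | category=<name>
#           | comp=<code>[,<code>...]
# Ranges are 1-based inclusive on auth_seq_id.  Chain ids match author chain
# id or subunit label.
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(r"^(chain|range|category|comp)=(\S+)$")


def _compile_clause(clause: str, position: int) -> Callable[[Residue, Chain], bool]:
    m = _CLAUSE_RE.match(clause.strip())
    if not m:
        raise SelectionError(f"cannot parse clause {clause.strip()!r}", position)
    key, value = m.groups()
    if key == "chain":
        wanted = set(value.split(","))
        return lambda r, c: c.chain_id in wanted or c.subunit_label in wanted
    if key == "range":
        rm = re.match(r"^(-?\d+)-(-?\d+)$", value)
        if not rm:
            raise SelectionError(f"bad range {value!r}", position)
        lo, hi = int(rm.group(1)), int(rm.group(2))
        if lo > hi:
            raise SelectionError(f"empty range {value!r} (start > end)", position)
        return lambda r, c: lo <= r.auth_seq_id <= hi
    if key == "category":
        if value not in comp.CATEGORIES:
            raise SelectionError(f"unknown category {value!r}", position)
        return lambda r, c: r.category == value
    # comp codes
    codes = {v.upper() for v in value.split(",")}
    return lambda r, c: r.comp_code.upper() in codes


def select_residues(model: StructureModel, expression: str) -> list[Residue]:
    """Evaluate a selection expression; result sorted by (chain, seq, icode)."""
    expression = expression.strip()
    if not expression:
        raise SelectionError("empty selection expression", 0)
    predicates = []
    pos = 0
    for part in re.split(r"\s+AND\s+", expression):
        predicates.append(_compile_clause(part, expression.find(part, pos)))
        pos = expression.find(part, pos) + len(part)
    out = []
    for c in model.chains:
        for r in c.residues:
            if all(p(r, c) for p in predicates):
                out.append(r)
    out.sort(key=lambda r: (r.chain_id, r.auth_seq_id, r.icode))
    return out
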