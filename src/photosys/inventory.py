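"""Cofactor census and per-site comparison between two models.

The census counts residues per functional category (and carotenoid
subtype), waters as molecules (one HOH residue = one water), and polymer
chains as chains holding at least one protein residue.  Two pigment sums
are reported: the four-class sum over Chl a + Chl b + beta-carotene +
lutein, and the all-class sum that additionally includes violaxanthin and
neoxanthin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import components as comp
from .model import StructureModel


@dataclass
class InventoryTable:
    polymer_chain_count: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)
    carotenoid_subtype_counts: dict[str, int] = field(default_factory=dict)
    water_count: int = 0
    pigment_sum: int = 0          # Chl a + Chl b + beta-carotene + lutein
    pigment_sum_all: int = 0      # + violaxanthin + neoxanthin
    per_chain: dict[str, dict[str, int]] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return self.category_counts.get(category, 0)

    def subtype_count(self, subtype: str) -> int:
        return self.carotenoid_subtype_counts.get(subtype, 0)

    def to_dict(self) -> dict:
        return {
            "polymer_chain_count": self.polymer_chain_count,
            "category_counts": dict(self.category_counts),
            "carotenoid_subtype_counts": dict(self.carotenoid_subtype_counts),
            "water_count": self.water_count,
            "pigment_sum": self.pigment_sum,
            "pigment_sum_all": self.pigment_sum_all,
            "per_chain": {k: dict(v) for k, v in self.per_chain.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["key\tcount",
                 f"polymer_chains\t{self.polymer_chain_count}"]
        for cat in comp.CATEGORIES:
            lines.append(f"{cat}\t{self.count(cat)}")
        for sub in comp.CAROTENOID_SUBTYPES:
            lines.append(f"carotenoid:{sub}\t{self.subtype_count(sub)}")
        lines.append(f"pigment_sum\t{self.pigment_sum}")
        lines.append(f"pigment_sum_all\t{self.pigment_sum_all}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CensusDiff:
    """Sites whose component assignment differs between two models."""
    entries: list[tuple[str, int, Optional[str], Optional[str]]] = \
        field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def empty(self) -> bool:
        return not self.entries

    def to_tsv(self, path: str | Path) -> None:
        lines = ["chain_id\tauth_seq_id\tcomp_code_a\tcomp_code_b"]
        for chain, seq, a, b in self.entries:
            lines.append(f"{chain}\t{seq}\t{a or '-'}\t{b or '-'}")
        Path(path).write_text("\n".join(lines) + "\n")


def cofactor_census(model: StructureModel) -> InventoryTable:
    """Count subunits, pigments, lipids, clusters and waters."""
    table = InventoryTable()
    cat_counts: dict[str, int] = {c: 0 for c in comp.CATEGORIES}
    sub_counts: dict[str, int] = {s: 0 for s in comp.CAROTENOID_SUBTYPES}
    for chain in model.chains:
        per_chain: dict[str, int] = {}
        for res in chain.residues:
            cat_counts[res.category] = cat_counts.get(res.category, 0) + 1
            per_chain[res.category] = per_chain.get(res.category, 0) + 1
            if res.category == comp.CAROTENOID and res.carotenoid_subtype:
                sub_counts[res.carotenoid_subtype] += 1
        table.per_chain[chain.chain_id] = per_chain
        if chain.is_polymer:
            table.polymer_chain_count += 1
    table.category_counts = cat_counts
    table.carotenoid_subtype_counts = sub_counts
    table.water_count = cat_counts.get(comp.WATER, 0)
    table.pigment_sum = (cat_counts[comp.CHL_A] + cat_counts[comp.CHL_B]
                         + sub_counts[comp.BETA_CAROTENE]
                         + sub_counts[comp.LUTEIN])
    table.pigment_sum_all = (table.pigment_sum
                             + sub_counts[comp.VIOLAXANTHIN]
                             + sub_counts[comp.NEOXANTHIN])
    return table


def compare_census(model_a: StructureModel, model_b: StructureModel,
                   chain_map: dict[str, str]) -> CensusDiff:
    """Per-site component diff between paired chains of two models.

    ``chain_map`` maps chain ids of ``model_a`` to chain ids of ``model_b``.
    A site is an (auth_seq_id, icode) within a paired chain; waters are
    excluded (they carry no stable site numbering across depositions).
    """
    diff = CensusDiff()
    for ca_id, cb_id in chain_map.items():
        ch_a = model_a.chain(ca_id)
        ch_b = model_b.chain(cb_id)
        if ch_a is None:
            raise KeyError(f"chain_map refers to absent chain {ca_id!r} in A")
        if ch_b is None:
            raise KeyError(f"chain_map refers to absent chain {cb_id!r} in B")
        sites_a = {(r.auth_seq_id, r.icode): r.comp_code
                   for r in ch_a.residues if r.category != comp.WATER}
        sites_b = {(r.auth_seq_id, r.icode): r.comp_code
                   for r in ch_b.residues if r.category != comp.WATER}
        for key in sorted(set(sites_a) | set(sites_b)):
            code_a = sites_a.get(key)
            code_b = sites_b.get(key)
            if code_a != code_b:
                diff.entries.append((ca_id, key[0], code_a, code_b))
    return diff
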