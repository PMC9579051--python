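"""Chemical-component classification.

Every residue in a parsed structure is assigned one of a small set of
functional categories (protein, the two chlorophyll species, carotenoids by
subtype, quinones, iron-sulfur clusters, lipids, water, other).  The mapping
from PDB chemical-component codes to categories lives in a
:class:`ComponentTable` so that users can extend it — depositions differ in
which lipid and detergent codes they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi

# Functional categories
PROTEIN = "protein"
CHL_A = "chlorophyll_a"
CHL_B = "chlorophyll_b"
CAROTENOID = "carotenoid"
QUINONE = "quinone"
METAL_CLUSTER = "metal_cluster"
LIPID = "lipid"
WATER = "water"
OTHER = "other"

CATEGORIES = (
    PROTEIN, CHL_A, CHL_B, CAROTENOID, QUINONE, METAL_CLUSTER, LIPID, WATER,
    OTHER,
)

# Carotenoid subtypes
BETA_CAROTENE = "beta_carotene"
LUTEIN = "lutein"
VIOLAXANTHIN = "violaxanthin"
NEOXANTHIN = "neoxanthin"

CAROTENOID_SUBTYPES = (BETA_CAROTENE, LUTEIN, VIOLAXANTHIN, NEOXANTHIN)

PIGMENT_CATEGORIES = frozenset({CHL_A, CHL_B, CAROTENOID, QUINONE})

#: default code -> (category, subtype) mapping for thylakoid-membrane
#: complexes.  Lipid codes cover the common thylakoid lipid classes
#: (galactolipids, sulfolipid, phosphatidylglycerol).
DEFAULT_MAPPING: dict[str, tuple[str, Optional[str]]] = {
    "CLA": (CHL_A, None),
    "CHL": (CHL_B, None),
    "BCR": (CAROTENOID, BETA_CAROTENE),
    "LUT": (CAROTENOID, LUTEIN),
    "XAT": (CAROTENOID, VIOLAXANTHIN),
    "NEX": (CAROTENOID, NEOXANTHIN),
    "PQN": (QUINONE, None),
    "SF4": (METAL_CLUSTER, None),
    "HOH": (WATER, None),
    "LMG": (LIPID, None),
    "LMU": (LIPID, None),
    "LHG": (LIPID, None),
    "SQD": (LIPID, None),
    "DGD": (LIPID, None),
    "PG": (LIPID, None),
}

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})


def _is_amino_acid(code: str) -> bool:
    info = gemmi.find_tabulated_residue(code)
    return info is not None and info.is_amino_acid()


@dataclass
class ComponentTable:
    """Total mapping from component codes to functional categories.

    Codes not present in the explicit mapping fall back to: amino acid →
    ``protein`` (via the tabulated residue dictionary), water codes →
    ``water``, anything else → ``other``.
    """

    mapping: dict[str, tuple[str, Optional[str]]] = field(
        default_factory=lambda: dict(DEFAULT_MAPPING))

    def classify(self, comp_code: str) -> tuple[str, Optional[str]]:
        code = comp_code.strip().upper()
        if code in self.mapping:
            return self.mapping[code]
        if code in WATER_CODES:
            return (WATER, None)
        if _is_amino_acid(code):
            return (PROTEIN, None)
        return (OTHER, None)

    def category(self, comp_code: str) -> str:
        return self.classify(comp_code)[0]

    def add(self, comp_code: str, category: str,
            subtype: Optional[str] = None) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if subtype is not None and subtype not in CAROTENOID_SUBTYPES:
            raise ValueError(f"unknown carotenoid subtype {subtype!r}")
        self.mapping[comp_code.strip().upper()] = (category, subtype)

    # -- plain-text config round trip ------------------------------------
    def to_config(self, path: str | Path) -> None:
        """Write the table as ``code<TAB>category[<TAB>subtype]`` lines."""
        lines = []
        for code in sorted(self.mapping):
            category, subtype = self.mapping[code]
            fields = [code, category] + ([subtype] if subtype else [])
            lines.append("\t".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ComponentTable":
        table = cls(mapping={})
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'code category [subtype]', "
                    f"got {line!r}")
            table.add(parts[0], parts[1], parts[2] if len(parts) == 3 else None)
        return table

    @classmethod
    def default(cls) -> "ComponentTable":
        return cls()


def unclassified_codes(comp_codes: Iterable[str],
                       table: ComponentTable) -> list[str]:
    """Hetero codes the table maps to ``other`` — candidates for extension."""
    seen = sorted({c.strip().upper() for c in comp_codes})
    return [c for c in seen if table.category(c) == OTHER]
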