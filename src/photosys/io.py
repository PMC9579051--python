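"""Reading and writing coordinate files (mmCIF and PDB, via gemmi).

Parsing policy: model 1 only; zero-occupancy atoms dropped; hydrogens
stripped (deposited models are heavy-atom; hydrogens only ever appear as
refinement artifacts); alternate locations resolved to the
highest-occupancy conformer, ties broken by altloc identifier.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import gemmi

from .components import ComponentTable
from .model import Atom, Chain, Residue, StructureModel, classify_components


class StructureParseError(ValueError):
    pass


class EmptyStructureError(StructureParseError):
    pass


def _infer_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    if any(s in (".pdb", ".ent") for s in suffixes):
        return "pdb"
    raise StructureParseError(
        f"cannot infer coordinate format from {path.name!r}; "
        "pass format='mmcif' or 'pdb'")


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties → lexicographically
    smallest altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.occ <= 0:
            continue
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ or (
                atom.occ == prev.occ
                and (atom.altloc or "") < (prev.altloc or "")):
            by_name[atom.name] = atom
    # preserve file order
    chosen = set(id(a) for a in by_name.values())
    return [a for a in res if id(a) in chosen]


def parse_structure(path: str | Path, format: str = "auto",
                    table: Optional[ComponentTable] = None,
                    keep_hydrogens: bool = False) -> StructureModel:
    """Read a coordinate file into a classified :class:`StructureModel`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path) if format == "auto" else format
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    st.setup_entities()
    table = table or ComponentTable()
    chains: list[Chain] = []
    n_atoms = 0
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    gmodel = st[0]  # model 1 only
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            atoms: list[Atom] = []
            for gatom in _resolve_altlocs(gres):
                element = gatom.element.name or "X"
                if not keep_hydrogens and element.upper() in ("H", "D"):
                    continue
                atoms.append(Atom(gatom.name, element,
                                  (gatom.pos.x, gatom.pos.y, gatom.pos.z),
                                  gatom.occ))
            if not atoms:
                continue
            n_atoms += len(atoms)
            seqid = gres.seqid
            residues.append(Residue(
                comp_code=gres.name,
                auth_seq_id=seqid.num if seqid.num is not None else 0,
                chain_id=gchain.name,
                icode=(seqid.icode or "").strip(),
                atoms=atoms))
        if residues:
            chains.append(Chain(gchain.name, residues=residues))
    if n_atoms == 0:
        raise EmptyStructureError(f"{path.name}: structure contains no atoms")
    model = StructureModel(chains, source_id=path.stem, component_table=table)
    return classify_components(model, table)


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    """Convert back to a gemmi Structure (used for writing)."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.comp_code
            gr.seqid = gemmi.SeqId(res.auth_seq_id, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*[round(float(x), 3) for x in a.pos])
                ga.occ = a.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_mmcif(model: StructureModel, path: str | Path) -> Path:
    """Write the model as mmCIF (coordinates rounded to 1e-3 Å)."""
    path = Path(path)
    st = to_gemmi(model)
    doc = st.make_mmcif_document()
    doc.write_file(str(path))
    return path
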