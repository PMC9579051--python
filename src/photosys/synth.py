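"""Synthetic coordinate fixtures with exact ground-truth manifests.

Generates toy membrane supercomplexes — ideal transmembrane helices
crossing a slab, minimal chlorophylls (Mg + four ring nitrogens + methine
carbons, no phytol tail), carotenoid and lipid stand-ins, and axial waters
— written as legal mmCIF so the real parser path is exercised end to end.
A C2 dimer variant plants a controlled interface: two
backbone-carbonyl-to-hydroxyl hydrogen bonds (related by the symmetry), a
symmetric side-chain amide bond pair, a lipid bridging cofactors of both
halves, and a single cross-monomer chlorophyll pair at a chosen Mg-Mg
distance.

Every manifest entry is computed from the generated coordinates by direct
brute-force scans inside this module, independent of the analysis modules
it is used to test.  The chemistry is deliberately minimal: these fixtures
validate geometry and bookkeeping, not molecular realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import components as comp
from .io import write_mmcif
from .model import Atom, Chain, Residue, StructureModel, classify_components


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    n_subunit_helices: int = 4
    helix_length: int = 24
    n_chl_a: int = 10
    n_chl_b: int = 10
    n_carotenoid: int = 4
    n_lipid: int = 3
    n_free_waters: int = 5
    water_coord_fraction_a: float = 0.2
    water_coord_fraction_b: float = 0.8
    slab_half_thickness: float = 15.0
    chl_z_max: float = 10.0          # bulk chlorophyll |z| bound
    cross_pair_distance: float = 15.0
    plant_interface: bool = True     # dimer only
    min_separation: float = 7.0      # between placed cofactor centres
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subunit_helices", "n_chl_a", "n_chl_b",
                     "n_carotenoid", "n_lipid", "n_free_waters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("water_coord_fraction_a", "water_coord_fraction_b"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # CA radius

#: bulk placement box for the monomer half (x kept > 16 so that C2-mirrored
#: chlorophyll images stay > 23 Å away and plant no accidental cross edges)
BOX_X = (16.0, 56.0)
BOX_Y = (-25.0, 25.0)


def ideal_helix_ca(n: int, origin: np.ndarray, phase: float = 0.0
                   ) -> np.ndarray:
    """CA trace of an ideal alpha helix along +z starting at ``origin``."""
    i = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST * i + phase)
    return np.column_stack([origin[0] + HELIX_RADIUS * np.cos(ang),
                            origin[1] + HELIX_RADIUS * np.sin(ang),
                            origin[2] + HELIX_RISE * i])


def _helix_residues(chain_id: str, n: int, origin: np.ndarray,
                    phase: float) -> list[Residue]:
    cas = ideal_helix_ca(n, origin, phase)
    i = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST * i + phase)
    res = []
    for k in range(n):
        c, s = math.cos(ang[k]), math.sin(ang[k])
        ca = cas[k]
        # schematic backbone partners around the CA (fixture geometry)
        atoms = [
            Atom("N", "N", ca + np.array([-0.8 * c, -0.8 * s, -1.1])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([0.7 * c, 0.7 * s, 1.0])),
            Atom("O", "O", ca + np.array([1.5 * c, 1.5 * s, 1.4])),
        ]
        res.append(Residue("ALA", k + 1, chain_id, atoms=atoms))
    return res


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _chlorophyll_residue(comp_code: str, seq: int, chain_id: str,
                         mg_pos: np.ndarray, orient: np.ndarray,
                         with_water: bool = False,
                         water_seq: int = 0
                         ) -> tuple[Residue, Optional[Residue]]:
    """Minimal chlorophyll: Mg + NA..ND at 2.05 Å + 4 methine carbons at
    3.0 Å, in the plane orthogonal to ``orient @ z``; optional axial water
    at 2.2 Å along the ring normal."""
    ex, ey, ez = orient[:, 0], orient[:, 1], orient[:, 2]
    atoms = [Atom("MG", "MG", mg_pos)]
    for name, d in (("NA", ex), ("NB", ey), ("NC", -ex), ("ND", -ey)):
        atoms.append(Atom(name, "N", mg_pos + 2.05 * d))
    for name, d in (("CHA", ex + ey), ("CHB", ey - ex),
                    ("CHC", -ex - ey), ("CHD", ex - ey)):
        atoms.append(Atom(name, "C", mg_pos + 3.0 * d / np.linalg.norm(d)))
    res = Residue(comp_code, seq, chain_id, atoms=atoms)
    water = None
    if with_water:
        water = Residue("HOH", water_seq, chain_id,
                        atoms=[Atom("O", "O", mg_pos + 2.2 * ez)])
    return res, water


def _carotenoid_residue(seq: int, chain_id: str, start: np.ndarray,
                        direction: np.ndarray, n_atoms: int = 8
                        ) -> Residue:
    d = direction / np.linalg.norm(direction)
    atoms = [Atom(f"C{i+1}", "C", start + 1.3 * i * d)
             for i in range(n_atoms)]
    return Residue("BCR", seq, chain_id, atoms=atoms)


def _lipid_residue(seq: int, chain_id: str, start: np.ndarray,
                   direction: np.ndarray, n_atoms: int = 6) -> Residue:
    d = direction / np.linalg.norm(direction)
    atoms = [Atom(f"C{i+1}", "C", start + 1.4 * i * d)
             for i in range(n_atoms)]
    atoms.append(Atom("O1", "O", start + np.array([0.0, 1.2, 0.0])))
    return Residue("LMG", seq, chain_id, atoms=atoms)


def _place(rng: np.random.Generator, occupied: list[np.ndarray],
           axes_xy: list[np.ndarray], min_sep: float,
           z_range: tuple[float, float],
           max_attempts: int = 1000) -> np.ndarray:
    """Rejection-sample a position keeping ``min_sep`` from occupied points
    (3D) and from helix axes (distance in the x-y plane)."""
    for _ in range(max_attempts):
        pos = np.array([rng.uniform(*BOX_X), rng.uniform(*BOX_Y),
                        rng.uniform(*z_range)])
        if any(np.linalg.norm(pos - q) < min_sep for q in occupied):
            continue
        if any(np.linalg.norm(pos[:2] - ax) < min_sep for ax in axes_xy):
            continue
        occupied.append(pos)
        return pos
    raise GenerationError(
        f"could not place a component after {max_attempts} attempts; "
        "reduce counts or enlarge the box")


# ---------------------------------------------------------------------------
# monomer
# ---------------------------------------------------------------------------

C2_ROTATION = np.diag([-1.0, -1.0, 1.0])   # 180° about z


def _sigma(p: np.ndarray) -> np.ndarray:
    return C2_ROTATION @ p


def _build_half(spec: SyntheticSpec, interface: bool
                ) -> tuple[list[Chain], dict]:
    """One monomer half in the x>0 region; returns chains + bookkeeping."""
    rng = np.random.default_rng(spec.seed)
    occupied: list[np.ndarray] = []
    axes_xy: list[np.ndarray] = []
    info: dict = {"tm_helices": [], "hydration_classes": {},
                  "special_sites": {}}
    if interface:
        # reserve the planted-feature region (see _plant_interface)
        r = spec.cross_pair_distance / 2.0
        occupied.extend([np.array([19.0, 1.5, -5.0]),    # CLA 810
                         np.array([r, 0.0, 10.0]),        # cross chlorophyll
                         np.array([7.0, -1.0, -6.0])])    # BCR 623

    chains: list[Chain] = []
    # --- protein helices, one chain each, crossing the slab -------------
    z0 = -HELIX_RISE * (spec.helix_length - 1) / 2.0
    for h in range(spec.n_subunit_helices):
        cid = chr(ord("A") + h)
        base = _place(rng, occupied, axes_xy,
                      max(spec.min_separation, 9.0), (z0, z0))
        occupied.pop()          # a helix is a column, not a point
        axes_xy.append(base[:2].copy())
        phase = float(rng.uniform(0, 360))
        chains.append(Chain(cid, residues=_helix_residues(
            cid, spec.helix_length, base, phase)))
        info["tm_helices"].append({"chain": cid, "start": 1,
                                   "end": spec.helix_length})

    cof = Chain("P")
    chains.append(cof)
    z_chl = (-spec.chl_z_max, spec.chl_z_max)

    def add_chl(code: str, seq: int, with_water: bool, wseq: int):
        pos = _place(rng, occupied, axes_xy, spec.min_separation, z_chl)
        res, water = _chlorophyll_residue(code, seq, "P", pos,
                                          random_rotation(rng),
                                          with_water, wseq)
        cof.residues.append(res)
        cls = "mono_hydrated" if with_water else "anhydrous"
        info["hydration_classes"][f"P:{code}:{seq}"] = cls
        return water

    waters: list[Residue] = []
    n_wet_a = round(spec.water_coord_fraction_a * spec.n_chl_a)
    n_wet_b = round(spec.water_coord_fraction_b * spec.n_chl_b)
    wseq = 1001
    for i in range(spec.n_chl_a):
        w = add_chl("CLA", 601 + i, i < n_wet_a, wseq)
        if w is not None:
            waters.append(w)
            wseq += 1
    for i in range(spec.n_chl_b):
        w = add_chl("CHL", 701 + i, i < n_wet_b, wseq)
        if w is not None:
            waters.append(w)
            wseq += 1
    for i in range(spec.n_carotenoid):
        pos = _place(rng, occupied, axes_xy, spec.min_separation, z_chl)
        cof.residues.append(_carotenoid_residue(630 + i, "P", pos,
                                                random_rotation(rng)[:, 0]))
    for i in range(spec.n_lipid):
        pos = _place(rng, occupied, axes_xy, spec.min_separation, z_chl)
        cof.residues.append(_lipid_residue(860 + i, "P", pos,
                                           random_rotation(rng)[:, 0]))
    for _ in range(spec.n_free_waters):
        pos = _place(rng, occupied, axes_xy, max(spec.min_separation, 6.0), z_chl)
        waters.append(Residue("HOH", wseq, "P",
                              atoms=[Atom("O", "O", pos)]))
        wseq += 1

    if interface:
        _plant_interface(spec, chains, cof, info)
    cof.residues.extend(waters)
    # freeze at mmCIF precision so every downstream manifest computation
    # (including the mirrored half: sign flips are exact) matches a re-parse
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.pos = np.round(atom.pos, 3)
    return chains, info


def _plant_interface(spec: SyntheticSpec, chains: list[Chain],
                     cof: Chain, info: dict) -> None:
    """Interface features, positioned so the C2 image completes each pair.

    Coordinates are in the final (dimer) frame; the mirrored copy provides
    the partner.  sigma() is the C2 operation (x,y -> -x,-y).
    """
    first = chains[0]
    # (1) backbone carbonyl (GLY, this half) -> hydroxyl (SER image)
    A = np.array([1.0, 4.0, 16.0])            # GLY O
    D = A + np.array([2.8, 0.0, 0.0])         # SER OG of the image half
    first.residues.append(Residue("GLY", 201, first.chain_id, atoms=[
        Atom("N", "N", A + np.array([-1.2, 1.2, 1.2])),
        Atom("CA", "C", A + np.array([-0.6, 0.6, 0.8])),
        Atom("C", "C", A + np.array([-0.4, 0.0, 0.6])),
        Atom("O", "O", A),
    ]))
    # SER whose image has OG at D; antecedent CB points away from A
    first.residues.append(Residue("SER", 210, first.chain_id, atoms=[
        Atom("N", "N", _sigma(D) + np.array([0.0, 0.0, -2.8])),
        Atom("CA", "C", _sigma(D) + np.array([0.0, 0.0, -1.6])),
        Atom("CB", "C", _sigma(D + np.array([1.4, 0.0, 0.0]))),
        Atom("OG", "O", _sigma(D)),
    ]))
    # (2) symmetric amide pair: NE2 at E donates to OE1 of the image, which
    # sits 2.9 Å above the image NE2 position
    a = 2.9 / (2.0 * math.sqrt(2.0))
    E = np.array([a, a, 6.0])
    first.residues.append(Residue("GLN", 220, first.chain_id, atoms=[
        Atom("N", "N", E + np.array([2.5, 2.5, -2.0])),
        Atom("CA", "C", E + np.array([1.5, 1.5, -1.3])),
        Atom("CD", "C", E + np.array([0.0, 0.0, -1.33])),
        Atom("NE2", "N", E),
        Atom("OE1", "O", _sigma(E) + np.array([0.0, 0.0, 2.9])),
    ]))
    info["special_sites"]["hbond_pairs"] = [
        [f"{first.chain_id}:GLY:201", f"{first.chain_id}2:SER:210"],
        [f"{first.chain_id}:SER:210", f"{first.chain_id}2:GLY:201"],
        [f"{first.chain_id}:GLN:220", f"{first.chain_id}2:GLN:220"],
        [f"{first.chain_id}2:GLN:220", f"{first.chain_id}:GLN:220"],
    ]
    # (3) bridging lipid along x, crossing the axis at z=-5
    lip_atoms = [Atom(f"C{i+1}", "C",
                      np.array([-4.0 + 1.4 * i, 1.5, -5.0]))
                 for i in range(13)]
    lip_atoms.append(Atom("O1", "O", np.array([-4.0, 2.7, -5.0])))
    cof.residues.append(Residue("LMG", 852, "P", atoms=lip_atoms))
    # chlorophyll 810 touching the +x lipid end
    res810, _ = _chlorophyll_residue("CLA", 810, "P",
                                     np.array([19.0, 1.5, -5.0]),
                                     np.eye(3))
    res810.atoms.append(Atom("CHE", "C", np.array([15.6, 2.2, -5.0])))
    cof.residues.append(res810)
    info["hydration_classes"]["P:CLA:810"] = "anhydrous"
    # beta-carotene 623 whose image touches the -x lipid end
    cof.residues.append(Residue("BCR", 623, "P", atoms=[
        Atom(f"C{i+1}", "C", np.array([7.0, -1.0, -9.0 + 1.0 * i]))
        for i in range(7)]))
    # (4) cross-monomer chlorophyll: Mg at half the pair distance from the
    # C2 axis, so Mg-to-image distance equals spec.cross_pair_distance
    r = spec.cross_pair_distance / 2.0
    res888, _ = _chlorophyll_residue("CLA", 888, "P",
                                     np.array([r, 0.0, 10.0]), np.eye(3))
    cof.residues.append(res888)
    info["hydration_classes"]["P:CLA:888"] = "anhydrous"
    info["special_sites"]["bridge"] = "P:LMG:852"
    info["special_sites"]["cross_pair"] = ["P:CLA:888", "P2:CLA:888"]


def _mirror_chains(chains: list[Chain]) -> list[Chain]:
    out = []
    for c in chains:
        residues = []
        for r in c.residues:
            atoms = [Atom(a.name, a.element, _sigma(a.pos), a.occupancy)
                     for a in r.atoms]
            residues.append(Residue(r.comp_code, r.auth_seq_id,
                                    c.chain_id + "2", r.icode,
                                    atoms=atoms))
        out.append(Chain(c.chain_id + "2", residues=residues))
    return out


# ---------------------------------------------------------------------------
# manifest bookkeeping (brute force, independent of the analysis modules)
# ---------------------------------------------------------------------------

def _site_id(res: Residue) -> str:
    return f"{res.chain_id}:{res.comp_code}:{res.auth_seq_id}"


def _census_of(chains: list[Chain], table: comp.ComponentTable) -> dict:
    counts = {c: 0 for c in comp.CATEGORIES}
    polymer = 0
    for chain in chains:
        has_protein = False
        for r in chain.residues:
            cat = table.category(r.comp_code)
            counts[cat] += 1
            has_protein = has_protein or cat == comp.PROTEIN
        polymer += has_protein
    counts["polymer_chain_count"] = polymer
    return counts


def _network_edges(chains: list[Chain], table: comp.ComponentTable,
                   cutoff: float) -> list[list]:
    chls = [r for c in chains for r in c.residues
            if table.category(r.comp_code) in (comp.CHL_A, comp.CHL_B)]
    edges = []
    for i in range(len(chls)):
        for j in range(i + 1, len(chls)):
            mi = next(a.pos for a in chls[i].atoms if a.element == "MG")
            mj = next(a.pos for a in chls[j].atoms if a.element == "MG")
            d = float(np.linalg.norm(mi - mj))
            if d <= cutoff:
                key = sorted([_site_id(chls[i]), _site_id(chls[j])])
                edges.append([key[0], key[1], round(d, 4)])
    edges.sort()
    return edges


def _interface_contacts_bruteforce(chains: list[Chain], cutoff: float
                                   ) -> list[list]:
    """Residue pairs across the two halves with any heavy-atom pair within
    cutoff (waters excluded)."""
    def half(c: Chain) -> int:
        return 2 if c.chain_id.endswith("2") else 1
    pairs = []
    res1 = [r for c in chains if half(c) == 1 for r in c.residues
            if r.comp_code != "HOH"]
    res2 = [r for c in chains if half(c) == 2 for r in c.residues
            if r.comp_code != "HOH"]
    for ra in res1:
        pa = ra.coords()
        for rb in res2:
            pb = rb.coords()
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :],
                               axis=2).min()
            if d <= cutoff:
                pairs.append([_site_id(ra), _site_id(rb), round(float(d), 4)])
    pairs.sort()
    return pairs


def _bridges_bruteforce(chains: list[Chain], table: comp.ComponentTable,
                        cutoff: float) -> list[str]:
    def half(c_id: str) -> int:
        return 2 if c_id.endswith("2") else 1
    all_res = [r for c in chains for r in c.residues]
    out = []
    for cand in all_res:
        cat = table.category(cand.comp_code)
        if cat in (comp.PROTEIN, comp.WATER):
            continue
        touched = {1: False, 2: False}
        pc = cand.coords()
        for other in all_res:
            if other is cand or table.category(other.comp_code) == comp.WATER:
                continue
            po = other.coords()
            d = np.linalg.norm(pc[:, None, :] - po[None, :, :], axis=2).min()
            if d <= cutoff:
                touched[half(other.chain_id)] = True
        if touched[1] and touched[2]:
            out.append(_site_id(cand))
    return sorted(out)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_monomer(spec: SyntheticSpec, out_path: str | Path
                     ) -> tuple[Path, dict]:
    """Write a monomer fixture as mmCIF and return (path, manifest)."""
    chains, info = _build_half(spec, interface=False)
    return _finalize(spec, chains, info, out_path, kind="monomer")


def generate_dimer(spec: SyntheticSpec, out_path: str | Path
                   ) -> tuple[Path, dict]:
    """Write a C2-dimer fixture (exact 180° copy about z) with a planted
    interface, as mmCIF, and return (path, manifest)."""
    half, info = _build_half(spec, interface=spec.plant_interface)
    chains = half + _mirror_chains(half)
    table = comp.ComponentTable()
    manifest_extra = {
        "grouping": {c.chain_id: ("M2" if c.chain_id.endswith("2") else "M1")
                     for c in chains},
        "c2": {"rotation": C2_ROTATION.tolist(),
               "translation": [0.0, 0.0, 0.0]},
        "monomer_census": _census_of(half, table),
        "cross_edges": [e for e in _network_edges(chains, table, 23.0)
                        if (e[0].split(":")[0].endswith("2"))
                        != (e[1].split(":")[0].endswith("2"))],
        "interface": {
            "contacts": _interface_contacts_bruteforce(chains, 4.0),
            "hbond_pairs": info["special_sites"].get("hbond_pairs", []),
            "bridges": _bridges_bruteforce(chains, table, 4.0),
        },
    }
    # mirrored hydration classes
    info["hydration_classes"].update({
        k.split(":")[0] + "2:" + k.split(":", 1)[1]: v
        for k, v in list(info["hydration_classes"].items())})
    info["tm_helices"] = info["tm_helices"] + [
        {"chain": h["chain"] + "2", "start": h["start"], "end": h["end"]}
        for h in info["tm_helices"]]
    return _finalize(spec, chains, info, out_path, kind="dimer",
                     extra=manifest_extra)


def _finalize(spec: SyntheticSpec, chains: list[Chain], info: dict,
              out_path: str | Path, kind: str,
              extra: Optional[dict] = None) -> tuple[Path, dict]:
    # freeze coordinates at mmCIF precision before manifest computation,
    # so manifest distances equal what a re-parse of the file yields
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.pos = np.round(atom.pos, 3)
    table = comp.ComponentTable()
    model = StructureModel(chains, source_id=f"synthetic_{kind}",
                           component_table=table)
    classify_components(model, table)
    out_path = Path(out_path)
    write_mmcif(model, out_path)

    classes = info["hydration_classes"]
    fa = [v for k, v in classes.items() if k.split(":")[1] == "CLA"]
    fb = [v for k, v in classes.items() if k.split(":")[1] == "CHL"]
    frac_a = (sum(v != "anhydrous" for v in fa) / len(fa)) if fa else 0.0
    frac_b = (sum(v != "anhydrous" for v in fb) / len(fb)) if fb else 0.0
    manifest = {
        "kind": kind,
        "spec": asdict(spec),
        "census": _census_of(chains, table),
        "tm_helices": info["tm_helices"],
        "hydration": {
            "classes": classes,
            "frac_a": frac_a,
            "frac_b": frac_b,
            "ratio": (frac_b / frac_a) if frac_a > 0 and fa and fb else None,
        },
        "network": {"cutoff": 23.0,
                    "edges": _network_edges(chains, table, 23.0)},
        "membrane_normal": [0.0, 0.0, 1.0],
    }
    if extra:
        manifest.update(extra)
    return out_path, manifest


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def rotated_slab_model(n_chl: int = 120, z_extent: float = 4.0,
                       spacing: float = 8.0, seed: int = 0
                       ) -> tuple[StructureModel, np.ndarray]:
    """Chlorophyll slab on a jittered grid, rigidly rotated by a recorded
    random rotation; returns (model, rotation).  The true membrane normal
    of the rotated model is ``rotation @ [0, 0, 1]``."""
    rng = np.random.default_rng(seed)
    side = math.ceil(math.sqrt(n_chl))
    pts = []
    for i in range(side):
        for j in range(side):
            if len(pts) >= n_chl:
                break
            pts.append([i * spacing + rng.uniform(-1, 1),
                        j * spacing + rng.uniform(-1, 1),
                        rng.uniform(-z_extent, z_extent)])
    pts = np.array(pts) - np.mean(pts, axis=0)
    R = random_rotation(rng)
    chain = Chain("P")
    for k, p in enumerate(pts @ R.T):
        res, _ = _chlorophyll_residue("CLA", 601 + k, "P", p,
                                      random_rotation(rng))
        chain.residues.append(res)
    model = StructureModel([chain], source_id="rotated_slab")
    classify_components(model)
    return model, R


def chlorophyll_cloud_model(n: int = 40, box: float = 60.0, seed: int = 0
                            ) -> StructureModel:
    """Random chlorophyll cloud (uniform in a cube) for oracle testing."""
    rng = np.random.default_rng(seed)
    chain = Chain("P")
    for k in range(n):
        pos = rng.uniform(0, box, size=3)
        code = "CLA" if rng.uniform() < 0.5 else "CHL"
        res, _ = _chlorophyll_residue(code, 601 + k, "P", pos,
                                      random_rotation(rng))
        chain.residues.append(res)
    model = StructureModel([chain], source_id="cloud")
    classify_components(model)
    return model
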