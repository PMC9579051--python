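"""Pipeline orchestration: run every analysis stage on one structure and
collect a consolidated, reproducible report."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .coordination import hydration_census
from .inventory import cofactor_census
from .io import parse_structure
from .membrane import (estimate_membrane_frame, detect_helices,
                       classify_tm_helices, max_extent,
                       InsufficientPigmentsError)
from .interface import interface_contacts
from .model import StructureModel
from .network import build_network, inter_group_edges


@dataclass
class AnalysisParameters:
    """All tunable thresholds of the pipeline, with their defaults.

    network_cutoff: Mg-Mg edge cutoff of the excitation network (Å).
    hbond_dmax / hbond_angle_min: geometric hydrogen-bond criterion.
    mg_ligand_cutoff: axial-ligand search radius around chlorophyll Mg (Å).
    contact_cutoff: heavy-atom residue-contact cutoff (Å).
    clash_tolerance: van der Waals overlap tolerance (Å).
    tm_min_span: minimum projected span of a transmembrane helix (Å).
    ensemble_max_angle: angular bound of the rigid-body ensemble (deg).
    histogram_bin: distance histogram bin width (Å).
    """

    network_cutoff: float = 23.0
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 90.0
    mg_ligand_cutoff: float = 2.9
    contact_cutoff: float = 4.0
    clash_tolerance: float = 0.4
    tm_min_span: float = 15.0
    ensemble_max_angle: float = 13.0
    histogram_bin: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if name != "seed" and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "AnalysisParameters":
        """Read ``key = value`` or ``key<TAB>value`` lines."""
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in
                     (line.split("=") if "=" in line else line.split())]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = parts
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            kwargs[key] = int(value) if key == "seed" else float(value)
        return cls(**kwargs)


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)      # stage -> reason
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"sections": self.sections, "skipped": self.skipped,
                "provenance": self.provenance}


def _log(quiet: bool, stage: str, t0: float) -> None:
    if not quiet:
        print(f"[photosys] {stage}: {time.perf_counter() - t0:.2f}s",
              file=sys.stderr)


def run_pipeline(structure_path: str | Path,
                 grouping: Optional[dict[str, str]] = None,
                 params: Optional[AnalysisParameters] = None,
                 model: Optional[StructureModel] = None,
                 quiet: bool = True) -> ReportBundle:
    """Run census, membrane/TM, hydration, network and (with a grouping)
    interface analysis; stages whose inputs are absent are skipped with a
    recorded reason."""
    params = params or AnalysisParameters()
    structure_path = Path(structure_path)
    if model is None:
        if not structure_path.exists():
            raise FileNotFoundError(f"input structure not found: "
                                    f"{structure_path}")
        model = parse_structure(structure_path)
    bundle = ReportBundle()
    bundle.provenance = {
        "input": str(structure_path),
        "grouping": grouping or {},
        "parameters": asdict(params),
        "photosys_version": __version__,
    }

    t0 = time.perf_counter()
    census = cofactor_census(model)
    bundle.sections["census"] = census.to_dict()
    _log(quiet, "census", t0)

    t0 = time.perf_counter()
    try:
        frame = estimate_membrane_frame(model)
        records = classify_tm_helices(detect_helices(model), frame,
                                      params.tm_min_span)
        bundle.sections["tm_helices"] = {
            "count": sum(r.is_tm for r in records),
            "n_segments": len(records),
            "helices": [{"chain": r.segment.chain_id,
                         "start": r.segment.start, "end": r.segment.end,
                         "span": round(r.span_along_normal, 2),
                         "is_tm": r.is_tm} for r in records],
        }
    except InsufficientPigmentsError as exc:
        bundle.skipped["tm_helices"] = str(exc)
    bundle.sections["max_extent"] = round(max_extent(model), 2)
    _log(quiet, "membrane", t0)

    t0 = time.perf_counter()
    if model.chlorophylls():
        stats = hydration_census(model, params.mg_ligand_cutoff)
        bundle.sections["hydration"] = {
            "n_chl_a": stats.n_chl_a, "n_chl_b": stats.n_chl_b,
            "frac_water_coordinated_a": stats.frac_water_coordinated_a,
            "frac_water_coordinated_b": stats.frac_water_coordinated_b,
            "ratio_b_over_a": stats.ratio_b_over_a,
            "n_di_hydrated": stats.n_di_hydrated,
        }
        graph = build_network(model, params.network_cutoff, grouping)
        section = {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges,
                   "cutoff": params.network_cutoff}
        if grouping:
            cross = inter_group_edges(graph)
            section["inter_group_edges"] = [
                {"a": "{}:{}:{}".format(e.a.site[0], e.a.site[2],
                                        e.a.site[1]),
                 "b": "{}:{}:{}".format(e.b.site[0], e.b.site[2],
                                        e.b.site[1]),
                 "distance": round(e.distance, 3)} for e in cross]
        bundle.sections["network"] = section
    else:
        bundle.skipped["hydration"] = "no chlorophylls in model"
        bundle.skipped["network"] = "no chlorophylls in model"
    _log(quiet, "network", t0)

    t0 = time.perf_counter()
    if grouping and len(set(grouping.values())) == 2:
        groups = sorted(set(grouping.values()))
        sel = {g: [r for c in model.chains if grouping.get(c.chain_id) == g
                   for r in c.residues] for g in groups}
        report = interface_contacts(model, sel[groups[0]], sel[groups[1]],
                                    params.contact_cutoff,
                                    params.hbond_dmax,
                                    params.hbond_angle_min)
        bundle.sections["interface"] = {
            "groups": groups, **report.summary,
            "bridges": ["{}:{}:{}".format(b.bridge.chain_id,
                                          b.bridge.comp_code,
                                          b.bridge.auth_seq_id)
                        for b in report.bridges],
        }
    else:
        bundle.skipped["interface"] = ("grouping with exactly two groups "
                                       "required")
    _log(quiet, "interface", t0)
    return bundle


def write_report(bundle: ReportBundle, path: str | Path,
                 format: str = "json") -> Path:
    """Write the bundle as one JSON file or a directory of TSV files.

    Deterministic: key order is sorted, so identical runs produce
    byte-identical output."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(bundle.to_dict(), indent=2,
                                   sort_keys=True, default=str) + "\n")
        return path
    if format == "tsv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for name, section in bundle.sections.items():
            out = path / f"{name}.tsv"
            if isinstance(section, dict):
                lines = [f"{k}\t{json.dumps(v, sort_keys=True, default=str)}"
                         for k, v in sorted(section.items())]
            else:
                lines = [f"{name}\t{section}"]
            out.write_text("\n".join(lines) + "\n")
        (path / "skipped.tsv").write_text(
            "\n".join(f"{k}\t{v}" for k, v in sorted(
                bundle.skipped.items())) + "\n")
        (path / "provenance.json").write_text(
            json.dumps(bundle.provenance, indent=2, sort_keys=True) + "\n")
        return path
    raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> ReportBundle:
    data = json.loads(Path(path).read_text())
    return ReportBundle(data["sections"], data["skipped"],
                        data["provenance"])


def read_grouping(path: str | Path) -> dict[str, str]:
    """chain-id → group-id TSV (two columns)."""
    grouping = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        chain, group = line.split("\t")[:2]
        grouping[chain] = group
    return grouping
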