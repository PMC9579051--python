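"""Membrane frame estimation and transmembrane-helix detection.

The thylakoid membrane plane is not recorded in a coordinate file, but the
chlorophylls of a light-harvesting supercomplex lie in a slab parallel to
it.  The membrane normal is therefore taken as the direction of least
variance of the chlorophyll Mg positions, with the origin at their
centroid.

Helices are detected from CA geometry alone (deposited models carry no
hydrogens, so hydrogen-bond-based secondary structure assignment is not
available): residue i is marked helical when its CA(i)-CA(i+3) and
CA(i)-CA(i+4) distances fall in the canonical alpha-helical windows.  A
segment is transmembrane when its ends project to opposite sides of the
membrane midplane and the projected span reaches ``min_span``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .model import StructureModel


class InsufficientPigmentsError(ValueError):
    pass


@dataclass
class MembraneFrame:
    origin: np.ndarray         # Mg centroid, Å
    normal: np.ndarray         # unit vector
    half_thickness: float = 15.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            self.normal = self.normal / n

    def project(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points from the midplane along the normal."""
        return (np.atleast_2d(points) - self.origin) @ self.normal


@dataclass
class HelixSegment:
    chain_id: str
    start: int                 # auth_seq_id, inclusive
    end: int
    ca_positions: np.ndarray   # (n, 3)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class TMHelixRecord:
    segment: HelixSegment
    span_along_normal: float
    crosses_midplane: bool
    is_tm: bool


def estimate_membrane_frame(model: StructureModel,
                            half_thickness: float = 15.0,
                            min_pigments: int = 10) -> MembraneFrame:
    """Least-variance plane of chlorophyll Mg positions.

    Requires at least ``min_pigments`` chlorophylls; for pigment-poor models
    supply a frame explicitly instead.
    """
    mgs = [r.mg.pos for r in model.chlorophylls() if r.mg is not None]
    if len(mgs) < min_pigments:
        raise InsufficientPigmentsError(
            f"membrane frame needs >= {min_pigments} chlorophyll Mg atoms, "
            f"found {len(mgs)}")
    pts = np.vstack(mgs)
    origin = pts.mean(axis=0)
    cov = np.cov((pts - origin).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest eigenvalue
    # sign convention: first chain's first CA projects non-negatively
    for chain in model.chains:
        ca = next((a for r in chain.residues for a in r.atoms
                   if a.name == "CA"), None)
        if ca is not None:
            if (ca.pos - origin) @ normal < 0:
                normal = -normal
            break
    return MembraneFrame(origin, normal, half_thickness)


def _chain_ca_series(chain) -> list[tuple[int, np.ndarray]]:
    out = []
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is not None:
            out.append((res.auth_seq_id, ca.pos))
    return out


def detect_helices(model: StructureModel,
                   d13: tuple[float, float] = (4.5, 6.0),
                   d14: tuple[float, float] = (5.7, 7.0),
                   min_len: int = 10) -> list[HelixSegment]:
    """CA-geometry helix detection.

    Residue i is helical iff |CA(i)-CA(i+3)| in ``d13`` and
    |CA(i)-CA(i+4)| in ``d14`` (both windows required, evaluated only where
    residues i..i+4 are contiguous in author numbering).  Maximal runs of at
    least ``min_len`` marked residues become segments; single-residue gaps
    are bridged, but runs are split across modelling gaps (author-numbering
    jumps > 1).
    """
    segments: list[HelixSegment] = []
    for chain in model.chains:
        series = _chain_ca_series(chain)
        if len(series) < 5:
            continue
        seqs = np.array([s for s, _ in series])
        pos = np.vstack([p for _, p in series])
        marked = np.zeros(len(series), bool)
        for i in range(len(series) - 4):
            if seqs[i + 4] - seqs[i] != 4:
                continue  # gap in author numbering
            a = np.linalg.norm(pos[i] - pos[i + 3])
            b = np.linalg.norm(pos[i] - pos[i + 4])
            if d13[0] <= a <= d13[1] and d14[0] <= b <= d14[1]:
                marked[i] = True
        # bridge single-residue holes inside marked runs (same numbering run)
        for i in range(1, len(series) - 1):
            if (not marked[i] and marked[i - 1] and marked[i + 1]
                    and seqs[i + 1] - seqs[i - 1] == 2):
                marked[i] = True
        # extract runs, splitting at numbering gaps > 1
        i = 0
        while i < len(series):
            if not marked[i]:
                i += 1
                continue
            j = i
            while (j + 1 < len(series) and marked[j + 1]
                   and seqs[j + 1] - seqs[j] <= 1):
                j += 1
            if j - i + 1 >= min_len:
                segments.append(HelixSegment(chain.chain_id,
                                             int(seqs[i]), int(seqs[j]),
                                             pos[i:j + 1].copy()))
            i = j + 1
    return segments


def classify_tm_helices(segments: list[HelixSegment], frame: MembraneFrame,
                        min_span: float = 15.0) -> list[TMHelixRecord]:
    """A segment is transmembrane iff its terminal CA projections straddle
    the midplane and span at least ``min_span`` Å along the normal."""
    records = []
    for seg in segments:
        proj = frame.project(seg.ca_positions)
        first, last = float(proj[0]), float(proj[-1])
        crosses = (first <= 0 <= last) or (last <= 0 <= first)
        span = abs(last - first)
        records.append(TMHelixRecord(seg, span, crosses,
                                     crosses and span >= min_span))
    return records


def tm_helix_count(model: StructureModel,
                   frame: Optional[MembraneFrame] = None,
                   min_span: float = 15.0) -> int:
    frame = frame or estimate_membrane_frame(model)
    return sum(r.is_tm
               for r in classify_tm_helices(detect_helices(model), frame,
                                            min_span))


def max_extent(model: StructureModel) -> float:
    """Maximum pairwise heavy-atom distance (Å), via the convex hull."""
    pts = model.heavy_coords()
    if len(pts) < 2:
        return 0.0
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (coplanar/collinear) — fall back to all points
    return float(pdist(pts).max())


def write_tm_tsv(records: list[TMHelixRecord], path: str | Path) -> None:
    lines = ["chain_id\tstart\tend\tspan_along_normal\tcrosses_midplane\tis_tm"]
    for r in records:
        lines.append(f"{r.segment.chain_id}\t{r.segment.start}\t"
                     f"{r.segment.end}\t{r.span_along_normal:.2f}\t"
                     f"{int(r.crosses_midplane)}\t{int(r.is_tm)}")
    Path(path).write_text("\n".join(lines) + "\n")
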