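"""Rigid-body flexibility ensembles and their PCA mode spectrum.

A dimer's two halves move as near-rigid bodies; this module simulates that
motion — random rotations of one chain group about a pivot, with an
angular bound (13 degrees by default, the scale of monomer-monomer
rocking seen in flexible photosynthetic dimers) — and provides the two
read-outs used to characterise such motion: distance histograms for
chosen cross-group site pairs, and the eigenvalue spectrum of a PCA over
the moving-group CA coordinates.

Rotation sampling is uniform in axis (on the sphere) and uniform in angle
on [0, max_angle]; this is not the Haar measure on SO(3), but the quantity
of interest is the angular bound, which this sampling makes explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel
from .superpose import kabsch


@dataclass
class EnsembleSpec:
    moving_chains: set[str]
    n_conformers: int = 100
    max_angle: float = 13.0          # degrees
    pivot: Optional[np.ndarray] = None   # default: interface centroid
    noise_sigma: float = 0.0         # Å, isotropic per-atom
    seed: int = 0

    def __post_init__(self):
        if self.n_conformers < 2:
            raise ValueError("need at least 2 conformers")
        if not 0 <= self.max_angle <= 180:
            raise ValueError("max_angle must be in [0, 180] degrees")


@dataclass
class Conformer:
    axis: np.ndarray
    angle: float                     # degrees
    coords: np.ndarray               # (n_moving_atoms, 3)


@dataclass
class PairDistanceSeries:
    pair: tuple
    distances: np.ndarray
    bin_width: float = 0.5

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def min(self) -> float:
        return float(self.distances.min())

    @property
    def max(self) -> float:
        return float(self.distances.max())

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_centers, counts) with fixed-width bins."""
        lo = np.floor(self.distances.min() / self.bin_width) * self.bin_width
        hi = np.ceil(self.distances.max() / self.bin_width) * self.bin_width
        edges = np.arange(lo, hi + self.bin_width, self.bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + self.bin_width])
        counts, edges = np.histogram(self.distances, bins=edges)
        return (edges[:-1] + self.bin_width / 2, counts)


@dataclass
class EnsembleSummary:
    series: list[PairDistanceSeries] = field(default_factory=list)
    eigenvalues: Optional[np.ndarray] = None     # descending
    variance_fractions: Optional[np.ndarray] = None
    top_k: int = 3
    degenerate: bool = False

    @property
    def top_k_variance(self) -> Optional[float]:
        if self.degenerate or self.variance_fractions is None:
            return None
        return float(self.variance_fractions[:self.top_k].sum())


@dataclass
class Ensemble:
    model: StructureModel
    spec: EnsembleSpec
    conformers: list[Conformer]
    pivot: np.ndarray
    atom_index: list[tuple]          # (residue key, atom name) per column
    rest_coords: np.ndarray          # moving-group coords of the input model
    ca_mask: np.ndarray              # boolean over moving atoms


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def interface_pivot(model: StructureModel, moving_chains: set[str],
                    radius: float = 8.0) -> np.ndarray:
    """Centroid of moving-group heavy atoms within ``radius`` of the static
    group — the natural hinge for a rigid-body rocking motion."""
    moving, static = [], []
    for chain in model.chains:
        dest = moving if chain.chain_id in moving_chains else static
        for r in chain.residues:
            dest.extend(a.pos for a in r.atoms if a.is_heavy)
    if not moving:
        raise ValueError("moving group has no atoms")
    moving_arr = np.vstack(moving)
    if not static:
        return moving_arr.mean(axis=0)
    tree = cKDTree(np.vstack(static))
    d, _ = tree.query(moving_arr, k=1)
    near = moving_arr[d <= radius]
    return near.mean(axis=0) if len(near) else moving_arr.mean(axis=0)


def _moving_atoms(model: StructureModel, moving_chains: set[str]):
    index, coords, ca_mask = [], [], []
    for chain in model.chains:
        if chain.chain_id not in moving_chains:
            continue
        for r in chain.residues:
            for a in r.atoms:
                if not a.is_heavy:
                    continue
                index.append((r.key, a.name))
                coords.append(a.pos)
                ca_mask.append(a.name == "CA")
    if not coords:
        raise ValueError(f"moving group {sorted(moving_chains)} is empty")
    return index, np.vstack(coords), np.array(ca_mask, bool)


def simulate_ensemble(model: StructureModel, spec: EnsembleSpec) -> Ensemble:
    """Sample rigid rotations of the moving group about the pivot.

    Deterministic for a fixed seed: same spec + seed → identical ensemble.
    """
    index, rest, ca_mask = _moving_atoms(model, spec.moving_chains)
    pivot = (np.asarray(spec.pivot, float) if spec.pivot is not None
             else interface_pivot(model, spec.moving_chains))
    rng = np.random.default_rng(spec.seed)
    conformers = []
    for _ in range(spec.n_conformers):
        v = rng.normal(size=3)
        while np.linalg.norm(v) < 1e-12:
            v = rng.normal(size=3)
        axis = v / np.linalg.norm(v)
        angle = rng.uniform(0.0, spec.max_angle)
        R = rotation_matrix(axis, angle)
        coords = (rest - pivot) @ R.T + pivot
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(scale=spec.noise_sigma,
                                         size=coords.shape)
        conformers.append(Conformer(axis, angle, coords))
    return Ensemble(model, spec, conformers, pivot, index, rest, ca_mask)


def _site_position(ensemble: Ensemble, site: tuple[str, int],
                   conformer: Optional[Conformer]) -> np.ndarray:
    """Mg position of a chlorophyll site, in the rest model or a conformer."""
    res = ensemble.model.find_residue(site[0], site[1])
    mg = res.mg
    if mg is None:
        raise KeyError(f"site {site} has no Mg atom (not a chlorophyll?)")
    if conformer is None or res.chain_id not in ensemble.spec.moving_chains:
        return mg.pos
    col = ensemble.atom_index.index((res.key, mg.name))
    return conformer.coords[col]


def pair_distance_series(ensemble: Ensemble,
                         pairs: Sequence[tuple[tuple[str, int],
                                               tuple[str, int]]],
                         bin_width: float = 0.5) -> EnsembleSummary:
    """Per-conformer distances for chosen site pairs, with 0.5 Å-bin
    histograms.  Sites are (chain_id, auth_seq_id) of chlorophylls."""
    summary = EnsembleSummary()
    for pair in pairs:
        ds = []
        for conf in ensemble.conformers:
            p = _site_position(ensemble, pair[0], conf)
            q = _site_position(ensemble, pair[1], conf)
            ds.append(float(np.linalg.norm(p - q)))
        summary.series.append(PairDistanceSeries(pair, np.array(ds),
                                                 bin_width))
    return summary


def pca_modes(ensemble: Ensemble, top_k: int = 3) -> EnsembleSummary:
    """PCA over flattened moving-group CA coordinates (per-atom centered).

    Eigenvalues are reported in descending order with the fraction of total
    variance in the top ``top_k`` modes; an ensemble of identical
    conformers has zero total variance and is flagged degenerate.
    """
    if len(ensemble.conformers) < 3:
        raise ValueError("PCA needs at least 3 conformers")
    X = np.stack([c.coords[ensemble.ca_mask].ravel()
                  for c in ensemble.conformers])
    if X.shape[1] == 0:   # no CA in moving group → use all heavy atoms
        X = np.stack([c.coords.ravel() for c in ensemble.conformers])
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum()) / (len(X) - 1)
    summary = EnsembleSummary(top_k=top_k)
    if total_var < 1e-12:
        summary.degenerate = True
        summary.eigenvalues = np.zeros(min(X.shape))
        summary.variance_fractions = None
        return summary
    # eigenvalues of the covariance via SVD of the centered data matrix
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = (s ** 2) / (len(X) - 1)
    summary.eigenvalues = eig
    summary.variance_fractions = eig / eig.sum()
    return summary


def estimate_max_angle(ensemble: Ensemble) -> float:
    """Recover the angular bound: re-derive each conformer's rotation by
    Kabsch against the rest coordinates and take the largest angle (deg)."""
    rest = ensemble.rest_coords - ensemble.pivot
    best = 0.0
    for conf in ensemble.conformers:
        R, _, _ = kabsch(rest, conf.coords - ensemble.pivot)
        cos = (np.trace(R) - 1.0) / 2.0
        best = max(best, float(np.degrees(np.arccos(np.clip(cos, -1, 1)))))
    return best


def write_histograms_tsv(summary: EnsembleSummary, path: str | Path) -> None:
    lines = ["pair\tbin_center\tcount"]
    for s in summary.series:
        centers, counts = s.histogram()
        name = (f"{s.pair[0][0]}{s.pair[0][1]}-"
                f"{s.pair[1][0]}{s.pair[1][1]}")
        for c, n in zip(centers, counts):
            lines.append(f"{name}\t{c:.2f}\t{int(n)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_eigenvalues_tsv(summary: EnsembleSummary, path: str | Path) -> None:
    lines = ["mode\teigenvalue\tvariance_fraction"]
    eig = summary.eigenvalues if summary.eigenvalues is not None else []
    for i, v in enumerate(eig, 1):
        frac = ("nan" if summary.variance_fractions is None
                else f"{summary.variance_fractions[i-1]:.6f}")
        lines.append(f"{i}\t{v:.6g}\t{frac}")
    Path(path).write_text("\n".join(lines) + "\n")
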