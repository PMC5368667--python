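"""Trajectory analysis: superposition/RMSD, greedy clustering, probe maps.

This module consumes multi-frame coordinate sets (e.g. stored snapshots of a
molecular dynamics run, read from multi-model PDB) and provides the three
analyses used to characterise an antibody domain's conformational ensemble
and surface hydrophobicity:

* optimal rigid-body superposition (Kabsch, proper rotations only) and
  pairwise RMSD matrices over a configurable atom selection;
* greedy dominant-structure clustering: repeatedly extract the frame with
  the most neighbours within an RMSD cutoff (default 0.2 nm) as a cluster
  centre together with those neighbours;
* hydrophobic probe-density maps: the mean number of probe particles within
  a cutoff (default 0.5 nm) of each protein heavy atom, averaged over
  frames, writable as a B-factor-coloured single-model PDB.

All coordinates are in nanometres internally; PDB files are angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Trajectory",
    "ClusterResult",
    "ProbeMap",
    "GreedyRMSDClustering",
    "superpose",
    "rmsd_matrix",
    "greedy_cluster",
    "probe_density",
    "write_map",
    "BACKBONE_NAMES",
    "PROBE_RESNAMES",
]

BACKBONE_NAMES = ("N", "CA", "C")
PROBE_RESNAMES = ("PRB", "CH4")

_ANGSTROM_PER_NM = 10.0


class GeometryError(ValueError):
    """Raised for degenerate superposition geometry."""


@dataclass
class Trajectory:
    """Frames of coordinates [nm] plus per-atom metadata.

    Probe particles are identified by residue name (``PRB``/``CH4`` by
    default); heavy atoms are non-hydrogen protein atoms.  ``box`` holds
    orthorhombic box edge lengths [nm] if the system is periodic.
    """

    coords: np.ndarray              # (n_frames, n_atoms, 3)
    atom_names: np.ndarray          # (n_atoms,)
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    box: np.ndarray | None = None   # (3,)
    probe_resnames: tuple[str, ...] = PROBE_RESNAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.coords.shape[1]
        for arr in (self.atom_names, self.elements, self.res_ids, self.res_names):
            if len(arr) != n:
                raise ValueError("atom metadata length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def is_probe(self) -> np.ndarray:
        return np.isin(self.res_names, self.probe_resnames)

    @property
    def is_heavy(self) -> np.ndarray:
        """Protein (non-probe) atoms that are not hydrogen."""
        return (~self.is_probe) & (np.char.upper(self.elements.astype(str)) != "H")

    def backbone_indices(self) -> np.ndarray:
        return np.nonzero(np.isin(self.atom_names, BACKBONE_NAMES) & ~self.is_probe)[0]

    # -- PDB I/O (multi-model; CRYST1 carries the box) --------------------
    @classmethod
    def from_pdb(cls, path: str | Path, probe_resnames: tuple[str, ...] = PROBE_RESNAMES) -> "Trajectory":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        box = None
        if stack.box is not None:
            box = np.diag(np.asarray(stack.box[0])) / _ANGSTROM_PER_NM
            if not np.any(box > 0):
                box = None
        return cls(
            coords=np.asarray(stack.coord) / _ANGSTROM_PER_NM,
            atom_names=np.asarray(stack.atom_name),
            elements=np.asarray(stack.element),
            res_ids=np.asarray(stack.res_id),
            res_names=np.asarray(stack.res_name),
            box=box,
            probe_resnames=probe_resnames,
        )

    def _atom_array(self, frame: int, b_factor: np.ndarray | None = None, mask=None) -> struc.AtomArray:
        mask = np.ones(self.n_atoms, bool) if mask is None else mask
        n = int(mask.sum())
        arr = struc.AtomArray(n)
        arr.coord = self.coords[frame][mask] * _ANGSTROM_PER_NM
        arr.atom_name = self.atom_names[mask]
        arr.element = self.elements[mask]
        arr.res_id = self.res_ids[mask]
        arr.res_name = self.res_names[mask]
        arr.chain_id = np.full(n, "A")
        arr.hetero = np.isin(self.res_names[mask], self.probe_resnames)
        arr.set_annotation(
            "b_factor",
            np.zeros(n) if b_factor is None else np.asarray(b_factor, float),
        )
        if self.box is not None:
            arr.box = np.diag(self.box * _ANGSTROM_PER_NM)
        return arr

    def to_pdb(self, path: str | Path) -> None:
        stack = struc.stack([self._atom_array(i) for i in range(self.n_frames)])
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch; proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` over
    the selected atoms; the RMSD is computed after the fit.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if selection is not None:
        ref, mob = ref[selection], mob[selection]
    if ref.shape != mob.shape:
        raise ValueError("selections differ in length")
    if len(ref) < 3:
        raise GeometryError("need at least 3 atoms for a unique rotation")
    ref_c, mob_c = ref.mean(axis=0), mob.mean(axis=0)
    P, Q = mob - mob_c, ref - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # Collinear selections leave the rotation about the axis undetermined.
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise GeometryError("degenerate geometry: selection is (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    fitted = P @ R.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_matrix(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Pairwise post-superposition RMSD [nm] over a selection (default backbone)."""
    if selection is None:
        selection = traj.backbone_indices()
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coords = traj.coords[:, selection, :]
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return mat


# ---------------------------------------------------------------------------
# Greedy dominant-structure clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray            # frame -> cluster id (0 = largest/first found)
    centers: tuple[int, ...]      # cluster id -> center frame index
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def greedy_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Dominant-structure clustering on a precomputed RMSD matrix.

    Repeatedly pick the unassigned frame with the most unassigned neighbours
    within ``cutoff`` (ties broken by lowest frame index), make it a centre,
    assign it and those neighbours to a new cluster, and remove them.
    """
    D = np.asarray(matrix, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("RMSD matrix contains NaN")
    n = D.shape[0]
    unassigned = np.ones(n, bool)
    labels = np.full(n, -1, int)
    centers: list[int] = []
    adjacency = D <= cutoff
    np.fill_diagonal(adjacency, True)
    while unassigned.any():
        counts = (adjacency & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = adjacency[center] & unassigned
        labels[members] = len(centers)
        centers.append(center)
        unassigned &= ~members
    return ClusterResult(labels=labels, centers=tuple(centers), cutoff=float(cutoff))


class GreedyRMSDClustering(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper: ``fit(D)`` on a precomputed RMSD matrix.

    Attributes: ``labels_``, ``centers_`` (frame indices), ``n_clusters_``.
    """

    def __init__(self, cutoff: float = 0.2):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        result = greedy_cluster(np.asarray(X, float), self.cutoff)
        self.labels_ = result.labels
        self.centers_ = result.centers
        self.n_clusters_ = result.n_clusters
        return self


# ---------------------------------------------------------------------------
# Hydrophobic probe-density mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMap:
    """Mean probe count near each heavy atom, averaged over frames."""

    heavy_indices: np.ndarray     # indices into the trajectory's atoms
    mean_counts: np.ndarray       # probes per frame, per heavy atom
    cutoff: float
    n_frames: int


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """All pairwise distances between point sets a (n,3) and b (m,3)."""
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta**2, axis=2))


def probe_density(traj: Trajectory, cutoff: float = 0.5) -> ProbeMap:
    """Mean number of probe particles within ``cutoff`` [nm] of each heavy atom.

    Distances use the minimum-image convention when the trajectory declares a
    periodic box; frames are treated as independent samples.
    """
    probe_idx = np.nonzero(traj.is_probe)[0]
    heavy_idx = np.nonzero(traj.is_heavy)[0]
    if probe_idx.size == 0:
        raise ValueError("trajectory contains no probe particles")
    if heavy_idx.size == 0:
        raise ValueError("trajectory contains no protein heavy atoms")
    if traj.box is not None and cutoff > traj.box.min() / 2:
        raise ValueError("cutoff exceeds half the smallest box length")
    totals = np.zeros(heavy_idx.size, dtype=np.int64)
    for frame in traj.coords:
        d = _pair_distances(frame[heavy_idx], frame[probe_idx], traj.box)
        totals += (d <= cutoff).sum(axis=1)
    return ProbeMap(
        heavy_indices=heavy_idx,
        mean_counts=totals / traj.n_frames,
        cutoff=float(cutoff),
        n_frames=traj.n_frames,
    )


def write_map(
    traj: Trajectory,
    probe_map: ProbeMap,
    path: str | Path,
    frame: int = 0,
    scale: tuple[float, float] = (0.0, 1.0),
) -> None:
    """Write one frame as a PDB with ``offset + gain * count`` in the B-factor.

    Probe particles are excluded; every written heavy atom must be covered by
    the map.  Hydrogens (if any) get a B-factor of 0.
    """
    heavy = np.nonzero(traj.is_heavy)[0]
    if not np.array_equal(np.sort(probe_map.heavy_indices), heavy):
        raise ValueError("probe map does not cover the structure's heavy atoms")
    offset, gain = scale
    b = np.zeros(traj.n_atoms)
    b[probe_map.heavy_indices] = offset + gain * probe_map.mean_counts
    mask = ~traj.is_probe
    arr = traj._atom_array(frame, b_factor=b[mask], mask=mask)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def cluster_assignments_frame(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"frame": np.arange(len(result.labels)), "cluster": result.labels}
    )
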