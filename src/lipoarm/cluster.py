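"""RMSD-matrix clustering and representative-structure selection.

Mirrors the pre-simulation structure selection workflow: a set of short
seeding trajectories is clustered on pairwise post-superposition RMSD with
the gmx-cluster neighbor-count algorithm, and the member of the largest
cluster with the smallest average RMSD to the rest of that cluster (the
centroid-most member) is taken as the representative structure.  All ties
break toward the lowest frame index, for determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .trajectory import Trajectory, kabsch_superpose, _resolve

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "gromos_cluster",
           "representative"]


@dataclass
class ClusterResult:
    """Frame partition: per-frame cluster id plus per-cluster member lists."""

    assignments: np.ndarray          # cluster id per frame
    clusters: list[np.ndarray]       # member frame indices, by cluster id
    representative_frame: int | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "sizes": self.sizes,
            "assignments": self.assignments.tolist(),
            "representative_frame": self.representative_frame,
        }, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def pairwise_rmsd_matrix(traj: Trajectory, selection=None) -> np.ndarray:
    """Symmetric matrix of post-superposition RMSDs between all frame pairs."""
    if traj.n_frames < 2:
        raise ParameterError("pairwise RMSD needs >= 2 frames")
    idx = _resolve(selection, traj.topology)
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(traj.coords[j], traj.coords[i], idx)
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Neighbor-count clustering on an RMSD matrix.

    Repeatedly the unassigned frame with the most unassigned neighbors within
    ``cutoff`` seeds a cluster of itself and those neighbors, which are then
    removed; neighbor-count ties break toward the lowest frame index.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=np.int64)
    clusters: list[np.ndarray] = []
    within = matrix <= cutoff
    np.fill_diagonal(within, False)
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))         # argmax returns lowest index tie
        members = np.flatnonzero(within[seed] & remaining)
        members = np.sort(np.append(members, seed))
        cid = len(clusters)
        assignments[members] = cid
        clusters.append(members)
        remaining[members] = False
    return ClusterResult(assignments=assignments, clusters=clusters)


def representative(clusters: ClusterResult, matrix: np.ndarray) -> int:
    """Centroid-most member of the largest cluster.

    Returns the member minimizing the average RMSD to all other members of
    the largest cluster; equal-size largest clusters resolve to the one
    containing the lowest frame index, and within-cluster ties to the lowest
    index (np.argmin convention).
    """
    if not clusters.clusters:
        raise ParameterError("no clusters to choose a representative from")
    sizes = clusters.sizes
    best_size = max(sizes)
    candidates = [c for c, s in zip(clusters.clusters, sizes) if s == best_size]
    largest = min(candidates, key=lambda c: int(c.min()))
    if len(largest) == 1:
        rep = int(largest[0])
    else:
        sub = np.asarray(matrix)[np.ix_(largest, largest)]
        avg = sub.sum(axis=1) / (len(largest) - 1)
        rep = int(largest[int(np.argmin(avg))])
    clusters.representative_frame = rep
    return rep
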