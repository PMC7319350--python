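"""RMSD clustering of conformer ensembles (GROMOS neighbor-count scheme).

The algorithm iterates: count, for every unassigned conformer, its
neighbours within the RMSD cutoff; the conformer with the most neighbours
becomes the medoid of a new cluster, it and its neighbours are removed, and
the process repeats until nothing is left.  Ties in neighbour count are
broken by the lowest ensemble index, making the result deterministic.
Defaults (1.25 Å cutoff on the 27 heavy atoms of SAM) match the clustering
granularity commonly used for this ligand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import (
    SAM_HEAVY_ATOMS,
    Conformer,
    ConformerEnsemble,
    interproton_distance,
)

__all__ = [
    "ClusterAssignment",
    "pairwise_rmsd_matrix",
    "cluster_gromos",
    "cluster_ensemble",
    "cluster_medoid_distances",
]

DEFAULT_CUTOFF = 1.25  # Å


@dataclass
class ClusterAssignment:
    """Cluster labels, medoids and populations over an ensemble.

    ``labels[i]`` is the cluster index of conformer i; ``medoid_indices[k]``
    is the ensemble index of cluster k's medoid (an actual ensemble member,
    the neighbour-count centre); ``populations[k]`` is the fraction of the
    ensemble in cluster k.
    """

    labels: np.ndarray
    medoid_indices: list[int]
    medoid_ids: list[str]
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        n_clusters = len(self.medoid_indices)
        if self.populations.shape != (n_clusters,):
            raise InvalidInputError("one population per cluster required")
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise InvalidInputError("cluster populations must sum to 1")
        for k, m in enumerate(self.medoid_indices):
            if self.labels[m] != k:
                raise InvalidInputError(f"medoid of cluster {k} is not a member of it")

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_indices)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "medoid_indices": list(self.medoid_indices),
            "medoid_ids": list(self.medoid_ids),
            "populations": self.populations.tolist(),
        }


def _centered_coords(
    ensemble: ConformerEnsemble | Sequence[Conformer], atom_subset: Sequence[str]
) -> np.ndarray:
    names = list(atom_subset)
    coords = np.empty((len(list(ensemble)), len(names), 3))
    for i, conf in enumerate(ensemble):
        coords[i] = conf.coords(names)  # raises MissingAtomError with the name
    return coords - coords.mean(axis=1, keepdims=True)


def _pair_rmsd_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum RMSD for batches of centered coordinate sets (Kabsch, batched).

    a, b: (n_pairs, m, 3) centered.  Uses the singular values of the
    cross-covariance: rmsd^2 = (tr(A A^T) + tr(B B^T) - 2 (s1+s2±s3)) / m,
    with the sign of s3 flipped for improper alignments.
    """
    m = a.shape[1]
    ga = np.einsum("pij,pij->p", a, a)
    gb = np.einsum("pij,pij->p", b, b)
    h = np.einsum("pik,pij->pkj", a, b)  # (n, 3, 3) cross-covariance
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.sign(np.linalg.det(h))
    sign[sign == 0] = 1.0
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    msd = np.maximum(ga + gb - 2.0 * trace, 0.0) / m
    return np.sqrt(msd)


def pairwise_rmsd_matrix(
    ensemble: ConformerEnsemble | Sequence[Conformer],
    atom_subset: Sequence[str] = SAM_HEAVY_ATOMS,
    chunk: int = 200_000,
) -> np.ndarray:
    """Symmetric matrix of pairwise heavy-atom RMSDs (Å).

    Each entry equals :func:`samconf.geometry.heavy_atom_rmsd` of the pair;
    superpositions are evaluated with a batched Kabsch solver so large
    ensembles stay tractable.
    """
    coords = _centered_coords(ensemble, atom_subset)
    n = coords.shape[0]
    if n == 0:
        raise InvalidInputError("pairwise RMSD of an empty ensemble")
    iu, ju = np.triu_indices(n, k=1)
    out = np.zeros((n, n))
    for start in range(0, iu.size, chunk):
        sl = slice(start, start + chunk)
        r = _pair_rmsd_batch(coords[iu[sl]], coords[ju[sl]])
        out[iu[sl], ju[sl]] = r
        out[ju[sl], iu[sl]] = r
    return out


def cluster_gromos(
    matrix: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Cluster a distance matrix with the GROMOS neighbour-count algorithm."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] == 0:
        raise InvalidInputError("distance matrix must be square and non-empty")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise InvalidInputError("distance matrix must be symmetric")
    if not cutoff > 0:
        raise InvalidInputError("cutoff must be > 0")
    n = mat.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise InvalidInputError("ids length must match matrix size")

    neighbours = mat <= cutoff  # includes self on the diagonal
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    medoids: list[int] = []
    while remaining.any():
        counts = (neighbours & remaining).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        cluster = neighbours[centre] & remaining
        k = len(medoids)
        labels[cluster] = k
        medoids.append(centre)
        remaining &= ~cluster
    populations = np.bincount(labels, minlength=len(medoids)) / n
    return ClusterAssignment(
        labels=labels,
        medoid_indices=medoids,
        medoid_ids=[ids[m] for m in medoids],
        populations=populations,
    )


def cluster_ensemble(
    ensemble: ConformerEnsemble | Sequence[Conformer],
    cutoff: float = DEFAULT_CUTOFF,
    atom_subset: Sequence[str] = SAM_HEAVY_ATOMS,
) -> ClusterAssignment:
    """Convenience wrapper: pairwise RMSD matrix + GROMOS clustering."""
    members = list(ensemble)
    matrix = pairwise_rmsd_matrix(members, atom_subset)
    return cluster_gromos(matrix, cutoff, ids=[c.id for c in members])


def cluster_medoid_distances(
    assignment: ClusterAssignment,
    ensemble: ConformerEnsemble | Sequence[Conformer],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Interproton distances of each cluster medoid for the given pairs.

    Returns a (n_clusters x n_pairs) DataFrame indexed by medoid id; these
    are the per-cluster distance vectors that enter the r^-6 population
    averaging.
    """
    members = list(ensemble)
    rows = []
    for m in assignment.medoid_indices:
        conf = members[m]
        rows.append([interproton_distance(conf, p) for p in pairs])
    cols = [f"{a}|{b}" for a, b in pairs]
    return pd.DataFrame(rows, index=list(assignment.medoid_ids), columns=cols)
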