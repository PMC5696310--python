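"""Reduction of docked ligand poses to representative medoids.

Docking typically produces tens of near-duplicate poses.  Before running MD
from them, the pose set is reduced in three steps: (1) a greedy mutual-RMSD
filter keeps at most ``max_poses`` poses no two of which are closer than a
cutoff; (2) PCA of the heavy-atom coordinates compresses the pose cloud to
the components explaining more than 5% of the variance; (3) k-means in
score space grows k while each extra cluster explains at least 5% more of
the variance, and each cluster's medoid is returned as the representative
pose.

RMSD is computed without superposition: all poses share the receptor frame,
and translational differences between binding modes are real signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "PoseCloud",
    "ClusterResult",
    "rmsd",
    "filter_poses",
    "pca_scores",
    "cluster_poses",
    "medoids",
    "select_binding_site_residues",
]


@dataclass
class PoseCloud:
    """n_poses x (3*n_atoms) heavy-atom coordinates (Å), common atom order/frame."""

    pose_ids: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or len(self.pose_ids) != self.coords.shape[0]:
            raise ValueError("coords must be n_poses x (3*n_atoms)")
        if self.coords.shape[1] % 3 or self.coords.shape[1] == 0:
            raise ValueError("coordinate row length must be a positive multiple of 3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1] // 3

    def __len__(self) -> int:
        return len(self.pose_ids)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    medoid_indices: list[int]
    medoid_pose_ids: list[str]
    explained_variance_by_k: list[float]


def rmsd(a, b) -> float:
    """Root-mean-square atomic deviation (Å) between two flattened poses.

    No superposition is performed: the poses are assumed to share the
    receptor coordinate frame.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n_atoms = a.size // 3
    if n_atoms < 1 or a.size % 3:
        raise ValueError("need >= 1 atom (length a multiple of 3)")
    d2 = ((a - b) ** 2).reshape(n_atoms, 3).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def filter_poses(
    cloud: PoseCloud,
    max_poses: int = 50,
    rmsd_cutoff: float = 2.0,
    scores=None,
) -> PoseCloud:
    """Greedy diversity filter: keep at most ``max_poses`` mutually distant poses.

    Poses are swept in ranking order — ascending docking score when
    ``scores`` is given (best pose first), else input order — and a pose is
    kept iff its RMSD to every already-kept pose is >= ``rmsd_cutoff``.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    order = (
        np.argsort(scores, kind="stable") if scores is not None else range(len(cloud))
    )
    kept: list[int] = []
    for i in order:
        if all(rmsd(cloud.coords[i], cloud.coords[j]) >= rmsd_cutoff for j in kept):
            kept.append(i)
            if len(kept) >= max_poses:
                break
    return PoseCloud([cloud.pose_ids[i] for i in kept], cloud.coords[kept])


def pca_scores(
    cloud: PoseCloud, var_threshold: float = 0.05
) -> tuple[np.ndarray, int]:
    """PCA of the pose coordinates; keep components explaining > threshold.

    Coordinates are mean-centred; components whose explained-variance
    fraction exceeds ``var_threshold`` are retained, with a floor of one
    component.  Returns the pose scores and the retained dimension.
    """
    if len(cloud) < 2:
        raise ValueError("PCA needs >= 2 poses")
    centred = cloud.coords - cloud.coords.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    variances = s**2
    total = variances.sum()
    if total == 0:
        # all poses identical: one degenerate component of zero scores
        return np.zeros((len(cloud), 1)), 1
    n_keep = max(int(np.sum(variances / total > var_threshold)), 1)
    return u[:, :n_keep] * s[:n_keep], n_keep


def _explained_fraction(scores: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster sum of squares over total sum of squares."""
    total = ((scores - scores.mean(axis=0)) ** 2).sum()
    if total == 0:
        return 1.0
    between = 0.0
    for lab in np.unique(labels):
        members = scores[labels == lab]
        between += len(members) * ((members.mean(axis=0) - scores.mean(axis=0)) ** 2).sum()
    return float(between / total)


def cluster_poses(
    scores: np.ndarray,
    var_gain: float = 0.05,
    seed: int = 0,
    n_restarts: int = 10,
    pose_ids: list[str] | None = None,
) -> ClusterResult:
    """Variance-driven k-means: grow k while each extra cluster pays its way.

    k starts at 1 and is incremented while the explained variance fraction
    (between-cluster over total sum of squares) improves by at least
    ``var_gain`` over k-1, up to the number of poses.  k-means runs with
    ``n_restarts`` seeded restarts, keeping the best inertia, so the result
    is deterministic given the seed.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n < 1:
        raise ValueError("need at least one score row")
    labels = np.zeros(n, dtype=int)
    if np.allclose(scores, scores[0], atol=1e-9):
        return ClusterResult(labels, 1, [0], [pose_ids[0]] if pose_ids else [], [1.0])
    trace = [_explained_fraction(scores, labels)]
    k = 1
    while k < n:
        n_distinct = len(np.unique(scores, axis=0))
        if k + 1 > n_distinct:
            break
        km = KMeans(
            n_clusters=k + 1, n_init=n_restarts, random_state=seed
        ).fit(scores)
        new_frac = _explained_fraction(scores, km.labels_)
        if new_frac - trace[-1] < var_gain:
            break
        labels = km.labels_.astype(int)
        trace.append(new_frac)
        k += 1
    med = medoids(scores, labels)
    return ClusterResult(
        labels=labels,
        k=k,
        medoid_indices=med,
        medoid_pose_ids=[pose_ids[i] for i in med] if pose_ids else [],
        explained_variance_by_k=trace,
    )


def medoids(scores: np.ndarray, labels) -> list[int]:
    """Per cluster, the member minimising total distance to its cluster.

    Clusters are visited in ascending label order; ties within a cluster go
    to the smallest pose index.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            raise ValueError(f"empty cluster {lab}")
        members = scores[idx]
        dists = np.linalg.norm(members[:, None, :] - members[None, :, :], axis=2)
        sums = dists.sum(axis=1)
        # tie tolerance: in 1-D score space the two central poses of an even
        # cluster tie exactly; smallest index wins regardless of ulp noise
        winners = np.flatnonzero(sums <= sums.min() + 1e-9)
        out.append(int(idx[winners[0]]))
    return out


def select_binding_site_residues(
    structure: dict[str, np.ndarray], center, cutoff: float = 16.0
) -> list[str]:
    """Residues with any heavy atom within ``cutoff`` Å of the site center.

    ``structure`` maps residue id to an (n_atoms, 3) heavy-atom coordinate
    array; residues are returned in structure order.  The boundary is
    inclusive (an atom at exactly the cutoff counts).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not structure:
        raise ValueError("empty structure")
    center = np.asarray(center, dtype=float)
    out = []
    for rid, atoms in structure.items():
        atoms = np.atleast_2d(np.asarray(atoms, dtype=float))
        if np.min(np.linalg.norm(atoms - center, axis=1)) <= cutoff:
            out.append(rid)
    return out
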