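"""Applicability domain (AD) calibration and reliability scoring.

A calibrated LIE model is only trusted inside the region of input space its
training set covered.  Five metrics delimit that region:

1. range of the training set's experimental binding free energies;
2. chemical similarity — maximum Tanimoto score against the training
   fingerprints, compared with a cutoff set to the lowest best-neighbour
   similarity observed within the training set;
3. the (dV_LJ, dV_Coul) interaction-energy distribution of the fitted
   simulations, summarised by centroid and covariance; queries must fall
   within the 95th percentile of training Mahalanobis distances;
4. per-residue Lennard-Jones interaction profiles (Boltzmann-weighted over
   poses), summarised by PCA; queries must have score distance (SD) and
   orthogonal distance (OD) within the training 95th percentiles;
5. the same for per-residue electrostatic profiles.

A query's reliability index is the number of metrics it violates: 0 means
fully inside the domain, 5 fully outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lie import CalibrationSet, LIEModel, PoseDescriptor

__all__ = [
    "Fingerprint",
    "EnergyDistributionRef",
    "ResiduePCARef",
    "ADReference",
    "ReliabilityReport",
    "tanimoto",
    "calibrate_ts_cutoff",
    "calibrate_energy_ref",
    "calibrate_residue_pca",
    "build_ad",
    "check_query",
]


@dataclass(frozen=True)
class Fingerprint:
    """A molecular fingerprint as a set of on-bit indices (e.g. MACCS keys)."""

    bits: frozenset[int]

    def __post_init__(self):
        if any((not isinstance(b, (int, np.integer))) or b <= 0 for b in self.bits):
            raise ValueError("fingerprint bits must be positive integers")

    @classmethod
    def from_bits(cls, bits) -> "Fingerprint":
        return cls(frozenset(int(b) for b in bits))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Set-overlap similarity |A∩B| / |A∪B|; 1.0 if both sets are empty."""
    union = a.bits | b.bits
    if not union:
        return 1.0
    return len(a.bits & b.bits) / len(union)


def calibrate_ts_cutoff(fps: list[Fingerprint]) -> float:
    """Similarity cutoff: the minimum over compounds of the best-neighbour TS.

    For each training compound the Tanimoto score with its most similar
    *other* training compound is recorded; the lowest of those maxima is the
    cutoff, so every training compound passes its own metric.
    """
    if len(fps) < 2:
        raise ValueError("need >= 2 fingerprints to calibrate a similarity cutoff")
    best = [
        max(tanimoto(fp, other) for j, other in enumerate(fps) if j != i)
        for i, fp in enumerate(fps)
    ]
    return float(min(best))


@dataclass
class EnergyDistributionRef:
    """Training (dV_LJ, dV_Coul) cloud: centroid, covariance, distance cutoff."""

    centroid: np.ndarray
    covariance: np.ndarray
    mahalanobis_cutoff: float
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.covariance)

    def distance(self, point) -> float:
        d = np.asarray(point, dtype=float) - self.centroid
        return float(np.sqrt(d @ self._cov_inv @ d))


def calibrate_energy_ref(
    selected: list[PoseDescriptor], percentile: float = 95.0
) -> EnergyDistributionRef:
    """Fit centroid/covariance of the fitted-pose energy points and set the cutoff.

    The cutoff is the empirical ``percentile`` (linear interpolation between
    order statistics) of the training points' Mahalanobis distances.  The
    sample covariance (n-1 denominator) must be non-singular.
    """
    pts = np.array([[p.dv_lj, p.dv_coul] for p in selected], dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 energy points")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("singular covariance of the energy distribution")
    ref = EnergyDistributionRef(centroid, cov, mahalanobis_cutoff=np.inf)
    dists = [ref.distance(p) for p in pts]
    ref.mahalanobis_cutoff = float(np.percentile(dists, percentile))
    return ref


@dataclass
class ResiduePCARef:
    """PCA summary of per-residue interaction profiles with SD/OD cutoffs.

    Components are retained while each explains more than ``var_threshold``
    of the original variance; if none does, the single largest is kept so
    the distances remain defined.  The score distance SD of a profile is
    SIMCA-style, sqrt(sum_k t_k^2 / lambda_k) over retained components with
    variances lambda_k; the orthogonal distance OD is the Euclidean norm of
    the reconstruction residual.
    """

    residue_ids: list[str]
    mean_vector: np.ndarray
    components: np.ndarray  # (n_retained, n_residues), orthonormal rows
    component_variances: np.ndarray
    sd_cutoff: float
    od_cutoff: float

    def project(self, profile) -> tuple[float, float]:
        """Return (score distance, orthogonal distance) for one residue profile."""
        x = np.asarray(profile, dtype=float)
        if x.shape != self.mean_vector.shape:
            raise ValueError(
                f"residue vector length {x.shape} != reference "
                f"{self.mean_vector.shape} ({len(self.residue_ids)} residues)"
            )
        centred = x - self.mean_vector
        scores = self.components @ centred
        sd = float(np.sqrt(np.sum(scores**2 / self.component_variances)))
        od = float(np.linalg.norm(centred - self.components.T @ scores))
        return sd, od


def calibrate_residue_pca(
    matrix: np.ndarray,
    residue_ids: list[str],
    var_threshold: float = 0.05,
    percentile: float = 95.0,
) -> ResiduePCARef:
    """PCA of a compounds x residues energy matrix with 95th-percentile cutoffs.

    Columns are mean-centred (no scaling).  Components with explained
    variance fraction > ``var_threshold`` are retained (at least one).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(residue_ids):
        raise ValueError("matrix shape does not match residue list")
    if x.shape[0] < 3:
        raise ValueError("need >= 3 compounds for residue PCA")
    mean = x.mean(axis=0)
    centred = x - mean
    # economy SVD: rows of vt are orthonormal loadings
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    variances = s**2 / (x.shape[0] - 1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("residue matrix has zero variance")
    frac = variances / total
    n_keep = int(np.sum(frac > var_threshold))
    n_keep = max(n_keep, 1)  # retention floor: SD/OD must stay defined
    ref = ResiduePCARef(
        residue_ids=list(residue_ids),
        mean_vector=mean,
        components=vt[:n_keep],
        component_variances=variances[:n_keep],
        sd_cutoff=np.inf,
        od_cutoff=np.inf,
    )
    sds, ods = zip(*(ref.project(row) for row in x))
    ref.sd_cutoff = float(np.percentile(sds, percentile))
    ref.od_cutoff = float(np.percentile(ods, percentile))
    return ref


@dataclass
class ADReference:
    """All five calibrated applicability-domain references.

    ``lj_residue_ref``/``coul_residue_ref`` may be ``None``, in which case
    metrics 4-5 are disabled and the reliability index runs over the
    remaining three metrics.
    """

    dg_min: float
    dg_max: float
    ts_cutoff: float
    energy_ref: EnergyDistributionRef
    training_fingerprints: list[Fingerprint]
    lj_residue_ref: ResiduePCARef | None = None
    coul_residue_ref: ResiduePCARef | None = None

    @property
    def n_metrics(self) -> int:
        return 3 + (self.lj_residue_ref is not None) + (
            self.coul_residue_ref is not None
        )


@dataclass
class ReliabilityReport:
    """Per-metric pass flags and the reliability index (count of failures)."""

    dg_range_ok: bool
    similarity_ok: bool
    energy_ok: bool
    lj_residue_ok: bool | None
    coul_residue_ok: bool | None

    @property
    def index(self) -> int:
        flags = [
            self.dg_range_ok,
            self.similarity_ok,
            self.energy_ok,
            self.lj_residue_ok,
            self.coul_residue_ok,
        ]
        return sum(1 for f in flags if f is False)

    def as_dict(self) -> dict:
        return {
            "dg_range_ok": self.dg_range_ok,
            "similarity_ok": self.similarity_ok,
            "energy_ok": self.energy_ok,
            "lj_residue_ok": self.lj_residue_ok,
            "coul_residue_ok": self.coul_residue_ok,
            "reliability_index": self.index,
        }


def _selected_descriptors(
    data: CalibrationSet, model: LIEModel
) -> list[PoseDescriptor]:
    """Pose descriptors the fitted model actually used (those carrying weights)."""
    out = []
    for c in data:
        w = model.training_weights.get(c.compound_id, {})
        out.extend(p for p in c.poses if p.pose_id in w)
    return out


def build_ad(
    data: CalibrationSet,
    model: LIEModel,
    fps: list[Fingerprint],
    residue_lj: np.ndarray | None = None,
    residue_coul: np.ndarray | None = None,
    residue_ids: list[str] | None = None,
) -> ADReference:
    """Calibrate the applicability domain of a fitted model.

    ``fps`` are the training fingerprints in compound order.  ``residue_lj``
    and ``residue_coul`` are compounds x residues matrices of Boltzmann-
    weighted per-residue energies; when omitted, metrics 4-5 are disabled.
    The energy-distribution metric is calibrated on the pose descriptors the
    model selected during fitting.
    """
    if len(fps) != len(data):
        raise ValueError("one fingerprint per training compound required")
    dg_obs = [c.dg_obs for c in data]
    lj_ref = coul_ref = None
    if residue_lj is not None or residue_coul is not None:
        if residue_lj is None or residue_coul is None or residue_ids is None:
            raise ValueError(
                "residue matrices require both lj and coul plus residue_ids"
            )
        lj_ref = calibrate_residue_pca(residue_lj, residue_ids)
        coul_ref = calibrate_residue_pca(residue_coul, residue_ids)
    return ADReference(
        dg_min=float(min(dg_obs)),
        dg_max=float(max(dg_obs)),
        ts_cutoff=calibrate_ts_cutoff(fps),
        energy_ref=calibrate_energy_ref(_selected_descriptors(data, model)),
        training_fingerprints=list(fps),
        lj_residue_ref=lj_ref,
        coul_residue_ref=coul_ref,
    )


def check_query(
    ref: ADReference,
    dg_pred: float,
    query_fp: Fingerprint,
    query_pose_descriptors: list[PoseDescriptor],
    query_residue_lj=None,
    query_residue_coul=None,
    energy_mode: str = "all_poses",
) -> ReliabilityReport:
    """Score one query compound against the five AD metrics.

    ``query_pose_descriptors`` are the model-selected poses of the query.
    With ``energy_mode='all_poses'`` (default, conservative) every selected
    pose point must lie within the Mahalanobis cutoff; ``'mean'`` tests the
    unweighted mean point instead.
    """
    dg_ok = ref.dg_min <= dg_pred <= ref.dg_max
    ts_ok = (
        max(tanimoto(query_fp, fp) for fp in ref.training_fingerprints)
        >= ref.ts_cutoff
    )
    pts = np.array([[p.dv_lj, p.dv_coul] for p in query_pose_descriptors])
    if pts.size == 0:
        raise ValueError("query has no pose descriptors")
    if energy_mode == "all_poses":
        energy_ok = all(
            ref.energy_ref.distance(pt) <= ref.energy_ref.mahalanobis_cutoff
            for pt in pts
        )
    elif energy_mode == "mean":
        energy_ok = (
            ref.energy_ref.distance(pts.mean(axis=0))
            <= ref.energy_ref.mahalanobis_cutoff
        )
    else:
        raise ValueError(f"unknown energy_mode {energy_mode!r}")

    def _residue_ok(r: ResiduePCARef | None, profile) -> bool | None:
        if r is None:
            return None
        if profile is None:
            raise ValueError("residue reference present but query profile missing")
        sd, od = r.project(profile)
        return sd <= r.sd_cutoff and od <= r.od_cutoff

    return ReliabilityReport(
        dg_range_ok=bool(dg_ok),
        similarity_ok=bool(ts_ok),
        energy_ok=bool(energy_ok),
        lj_residue_ok=_residue_ok(ref.lj_residue_ref, query_residue_lj),
        coul_residue_ok=_residue_ok(ref.coul_residue_ref, query_residue_coul),
    )
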