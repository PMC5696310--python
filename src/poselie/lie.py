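"""Iterative Boltzmann-weighted linear interaction energy (LIE) modelling.

The LIE ansatz estimates the binding free energy of a ligand from the
bound-minus-free differences of its ensemble-average Lennard-Jones and
Coulomb interaction energies with the surroundings,

    dG = alpha * dV_LJ + beta * dV_Coul (+ gamma),

with empirical coefficients alpha, beta and an optional constant offset
gamma (kJ/mol).  When several docked poses are simulated per compound the
per-pose estimates are combined with Boltzmann weights

    W_i = exp(-dG_i / kB T) / sum_j exp(-dG_j / kB T),

so that the combined prediction is dominated self-consistently by the most
favourable poses.  Because the weights depend on the coefficients and vice
versa, calibration alternates weight computation and least-squares fitting
until the coefficients converge (a fixed-point iteration).

Model selection keeps, per compound, the j poses with the lowest predicted
dG and picks the j minimising the standard deviation error in prediction
(SDEP) under leave-one-out cross-validation.

All energies are kJ/mol throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("poselie")

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.0083144621

#: Default temperature (K) matching typical MD production conditions.
DEFAULT_TEMPERATURE = 300.0


class ConvergenceError(RuntimeError):
    """Raised when the fixed-point iteration fails to converge.

    Carries the coefficient trajectory in :attr:`trajectory` (one row of
    coefficients per iteration) for diagnosis.
    """

    def __init__(self, message: str, trajectory: np.ndarray):
        super().__init__(message)
        self.trajectory = trajectory


class RankDeficientError(ValueError):
    """Raised when the weighted descriptor matrix loses full column rank."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyRecord:
    """One replicate simulation's ligand-surroundings energy averages.

    ``pose_id`` is ``None`` for the free (solvated, unbound) state.
    """

    compound_id: str
    pose_id: str | None
    replicate_id: int
    v_lj: float
    v_coul: float

    def __post_init__(self):
        if not (np.isfinite(self.v_lj) and np.isfinite(self.v_coul)):
            raise ValueError(
                f"non-finite energy for compound {self.compound_id!r} "
                f"pose {self.pose_id!r} replicate {self.replicate_id}"
            )
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be >= 1")


@dataclass(frozen=True)
class PoseDescriptor:
    """Replicate-averaged bound-minus-free LJ/Coulomb differences for one pose."""

    compound_id: str
    pose_id: str
    dv_lj: float
    dv_coul: float


@dataclass(frozen=True)
class LIEParams:
    """Fitted LIE coefficients; ``gamma`` only meaningful when ``include_gamma``."""

    alpha: float
    beta: float
    gamma: float = 0.0
    include_gamma: bool = False

    def as_array(self) -> np.ndarray:
        if self.include_gamma:
            return np.array([self.alpha, self.beta, self.gamma])
        return np.array([self.alpha, self.beta])


@dataclass(frozen=True)
class ThermodynamicConstants:
    k_b: float = KB
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return self.k_b * self.temperature


@dataclass
class Compound:
    """One calibration compound: observed dG and its pose descriptors."""

    compound_id: str
    dg_obs: float
    poses: list[PoseDescriptor]

    def __post_init__(self):
        if not self.poses:
            raise ValueError(f"compound {self.compound_id!r} has no poses")
        if not np.isfinite(self.dg_obs):
            raise ValueError(f"compound {self.compound_id!r} has non-finite dg_obs")


@dataclass
class CalibrationSet:
    compounds: list[Compound]

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def subset(self, indices) -> "CalibrationSet":
        return CalibrationSet([self.compounds[i] for i in indices])

    def restrict_poses(self, keep: dict[str, list[str]]) -> "CalibrationSet":
        """Return a copy keeping, per compound, only the listed pose_ids (in order)."""
        out = []
        for c in self.compounds:
            wanted = keep.get(c.compound_id)
            if wanted is None:
                out.append(c)
                continue
            by_id = {p.pose_id: p for p in c.poses}
            out.append(Compound(c.compound_id, c.dg_obs, [by_id[p] for p in wanted]))
        return CalibrationSet(out)


@dataclass
class FitOptions:
    include_gamma: bool = False
    init_params: LIEParams | None = None
    tol: float = 1e-6
    max_iter: int = 500
    constants: ThermodynamicConstants = field(default_factory=ThermodynamicConstants)

    def initial(self) -> LIEParams:
        if self.init_params is not None:
            p = self.init_params
            return LIEParams(p.alpha, p.beta, p.gamma, self.include_gamma)
        return LIEParams(0.5, 0.5, 0.0, self.include_gamma)


@dataclass
class LIEModel:
    """A calibrated multi-pose LIE model."""

    params: LIEParams
    n_poses: int
    training_stats: dict[str, float]
    constants: ThermodynamicConstants
    training_weights: dict[str, dict[str, float]]


@dataclass
class Prediction:
    compound_id: str
    dg_bind: float
    weights: dict[str, float]
    per_pose_dg: dict[str, float]
    n_poses_used: int


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------


def average_replicates(records: list[EnergyRecord]) -> list[PoseDescriptor]:
    """Average replicate runs and form bound-minus-free pose descriptors.

    Each bound pose's LJ/Coulomb averages are the unweighted mean over its
    replicates; the compound's free-state mean is subtracted.  A pose with a
    single replicate triggers a warning but is processed normally.

    Raises
    ------
    ValueError
        If a compound with bound records has no free-state record, or on
        duplicate (compound, pose, replicate) keys.
    """
    seen: set[tuple] = set()
    bound: dict[tuple[str, str], list[EnergyRecord]] = {}
    free: dict[str, list[EnergyRecord]] = {}
    for r in records:
        key = (r.compound_id, r.pose_id, r.replicate_id)
        if key in seen:
            raise ValueError(f"duplicate record {key}")
        seen.add(key)
        if r.pose_id is None:
            free.setdefault(r.compound_id, []).append(r)
        else:
            bound.setdefault((r.compound_id, r.pose_id), []).append(r)

    missing = sorted({c for (c, _) in bound} - set(free))
    if missing:
        raise ValueError(
            "missing free-state record for compound(s): " + ", ".join(missing)
        )

    out: list[PoseDescriptor] = []
    for (cid, pid), reps in bound.items():
        if len(reps) == 1:
            warnings.warn(
                f"pose {pid!r} of compound {cid!r} has a single replicate",
                stacklevel=2,
            )
        fr = free[cid]
        dv_lj = np.mean([r.v_lj for r in reps]) - np.mean([r.v_lj for r in fr])
        dv_coul = np.mean([r.v_coul for r in reps]) - np.mean([r.v_coul for r in fr])
        out.append(PoseDescriptor(cid, pid, float(dv_lj), float(dv_coul)))
    return out


# ---------------------------------------------------------------------------
# Elementary LIE algebra
# ---------------------------------------------------------------------------


def pose_dg(params: LIEParams, pose: PoseDescriptor) -> float:
    """Single-pose LIE free energy alpha*dV_LJ + beta*dV_Coul (+ gamma)."""
    dg = params.alpha * pose.dv_lj + params.beta * pose.dv_coul
    if params.include_gamma:
        dg += params.gamma
    return dg


def boltzmann_weights(
    dg_values, constants: ThermodynamicConstants = ThermodynamicConstants()
) -> np.ndarray:
    """Normalised Boltzmann weights exp(-dG_i/kBT)/sum, max-shifted for stability.

    The weights are invariant under adding a constant to every dG_i.
    """
    dg = np.asarray(dg_values, dtype=float)
    if dg.size == 0:
        raise ValueError("empty dG list")
    if not np.all(np.isfinite(dg)):
        raise ValueError("non-finite dG value")
    x = -(dg - dg.min()) / constants.kt
    w = np.exp(x)
    return w / w.sum()


def weighted_descriptors(poses: list[PoseDescriptor], weights) -> tuple[float, float]:
    """Boltzmann-weighted sums (sum W_i dV_LJ_i, sum W_i dV_Coul_i)."""
    w = np.asarray(weights, dtype=float)
    if len(poses) != w.size:
        raise ValueError(f"{len(poses)} poses but {w.size} weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights do not sum to 1")
    dv_lj = float(np.dot(w, [p.dv_lj for p in poses]))
    dv_coul = float(np.dot(w, [p.dv_coul for p in poses]))
    return dv_lj, dv_coul


# ---------------------------------------------------------------------------
# Iterative fitting
# ---------------------------------------------------------------------------


def _design_matrix(
    data: CalibrationSet, params: LIEParams, constants: ThermodynamicConstants
):
    """Weighted descriptor rows under the current params, plus the weights used."""
    rows = []
    weights: dict[str, dict[str, float]] = {}
    for c in data:
        dgs = [pose_dg(params, p) for p in c.poses]
        w = boltzmann_weights(dgs, constants)
        weights[c.compound_id] = {p.pose_id: float(wi) for p, wi in zip(c.poses, w)}
        rows.append(weighted_descriptors(c.poses, w))
    return np.array(rows), weights


def _ls_fit(x: np.ndarray, y: np.ndarray, include_gamma: bool) -> LIEParams:
    """Unregularised least squares of y on (dV_LJ_w, dV_Coul_w[, 1])."""
    a = np.column_stack([x, np.ones(len(x))]) if include_gamma else x
    # a constant descriptor column makes its coefficient act as a hidden
    # offset and corrupts the pose weights, so it is rejected outright
    names = ["dv_lj", "dv_coul"]
    bad = [
        names[j] for j in range(2) if np.allclose(x[:, j], x[0, j], atol=1e-12)
    ]
    if bad or np.linalg.matrix_rank(a) < a.shape[1]:
        detail = f" (constant column: {', '.join(bad)})" if bad else ""
        raise RankDeficientError(f"rank-deficient design matrix{detail}")
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    if include_gamma:
        return LIEParams(float(coef[0]), float(coef[1]), float(coef[2]), True)
    return LIEParams(float(coef[0]), float(coef[1]), 0.0, False)


def fit_lie_iterative(
    data: CalibrationSet, options: FitOptions | None = None
) -> tuple[LIEParams, dict[str, dict[str, float]]]:
    """Fit alpha, beta (and optionally gamma) by fixed-point iteration.

    Starting from the initial coefficients, each step (1) evaluates every
    pose's dG, (2) turns them into Boltzmann weights per compound, (3) forms
    the weighted descriptor sums and (4) refits the coefficients by least
    squares on the observed dG.  Stops when the largest absolute coefficient
    change drops below ``tol``.

    Returns the converged parameters and the final per-compound pose weights.
    """
    options = options or FitOptions()
    n_min = 3 if options.include_gamma else 2
    if len(data) < n_min:
        raise ValueError(f"need >= {n_min} compounds, got {len(data)}")
    y = np.array([c.dg_obs for c in data])
    params = options.initial()
    traj = [params.as_array()]
    for _ in range(options.max_iter):
        x, weights = _design_matrix(data, params, options.constants)
        new = _ls_fit(x, y, options.include_gamma)
        traj.append(new.as_array())
        delta = np.max(np.abs(new.as_array() - params.as_array()))
        params = new
        if delta < options.tol:
            # recompute weights under the converged coefficients
            _, weights = _design_matrix(data, params, options.constants)
            return params, weights
    raise ConvergenceError(
        f"no convergence after {options.max_iter} iterations "
        f"(last step {delta:.3e} > tol {options.tol:.1e})",
        np.array(traj),
    )


# ---------------------------------------------------------------------------
# Pose ranking, LOO SDEP and model selection
# ---------------------------------------------------------------------------


def rank_poses(
    data: CalibrationSet,
    params: LIEParams,
    constants: ThermodynamicConstants = ThermodynamicConstants(),
) -> dict[str, list[str]]:
    """Per compound, pose_ids sorted by ascending pose dG; ties by pose_id."""
    del constants  # ranking needs only the per-pose dG ordering
    out = {}
    for c in data:
        keyed = sorted(c.poses, key=lambda p: (pose_dg(params, p), p.pose_id))
        out[c.compound_id] = [p.pose_id for p in keyed]
    return out


def predict_dg(model: LIEModel, poses: list[PoseDescriptor]) -> Prediction:
    """Predict a query compound's binding free energy.

    Poses are ranked by their single-pose dG under the model coefficients,
    the ``model.n_poses`` lowest are kept (all, if fewer are available), and
    the Boltzmann-weighted combination gives dG_bind.
    """
    if not poses:
        raise ValueError("no poses supplied for prediction")
    params = model.params
    ranked = sorted(poses, key=lambda p: (pose_dg(params, p), p.pose_id))
    kept = ranked[: min(model.n_poses, len(ranked))]
    dgs = [pose_dg(params, p) for p in kept]
    w = boltzmann_weights(dgs, model.constants)
    dv_lj_w, dv_coul_w = weighted_descriptors(kept, w)
    dg = params.alpha * dv_lj_w + params.beta * dv_coul_w
    if params.include_gamma:
        dg += params.gamma
    return Prediction(
        compound_id=kept[0].compound_id,
        dg_bind=float(dg),
        weights={p.pose_id: float(wi) for p, wi in zip(kept, w)},
        per_pose_dg={p.pose_id: float(d) for p, d in zip(kept, dgs)},
        n_poses_used=len(kept),
    )


def _predict_with_params(
    params: LIEParams,
    n_poses: int,
    constants: ThermodynamicConstants,
    poses: list[PoseDescriptor],
) -> float:
    model = LIEModel(params, n_poses, {}, constants, {})
    return predict_dg(model, poses).dg_bind


def loo_sdep(
    data: CalibrationSet, options: FitOptions | None = None, n_poses: int | None = None
) -> float:
    """Leave-one-out SDEP: RMS of held-out prediction errors.

    Every fold refits the iterative model from scratch (default
    initialisation) on the remaining compounds; the held-out compound is
    predicted with the fold's coefficients.  ``n_poses`` caps how many
    lowest-dG poses each prediction may combine (default: all available).
    """
    options = options or FitOptions()
    if len(data) < 3:
        raise ValueError("leave-one-out needs >= 3 compounds")
    errors = []
    for i, held in enumerate(data.compounds):
        rest = data.subset([j for j in range(len(data)) if j != i])
        try:
            params, _ = fit_lie_iterative(rest, options)
        except (ConvergenceError, RankDeficientError) as exc:
            raise type(exc)(
                f"LOO fold holding out {held.compound_id!r} failed: {exc}",
                *( (exc.trajectory,) if isinstance(exc, ConvergenceError) else () ),
            ) from exc
        k = n_poses if n_poses is not None else len(held.poses)
        pred = _predict_with_params(params, k, options.constants, held.poses)
        errors.append(pred - held.dg_obs)
    return float(np.sqrt(np.mean(np.square(errors))))


def calibrate_model(
    data: CalibrationSet, options: FitOptions | None = None
) -> LIEModel:
    """Full calibration: fit, rank poses, select the pose count by LOO SDEP.

    A first fit on all poses provides the coefficients used to rank each
    compound's poses by dG.  For j = 1 .. max pose count, each compound keeps
    its j lowest-dG poses (all, if it has fewer), the model is refitted on
    the restricted set and its LOO SDEP computed.  The model with the lowest
    SDEP wins; ties go to the smaller j.  The pose ranking from the full fit
    is reused across the j-sweep (no re-ranking inside the sweep).
    """
    options = options or FitOptions()
    full_params, _ = fit_lie_iterative(data, options)
    ranking = rank_poses(data, full_params, options.constants)
    max_j = max(len(c.poses) for c in data)

    best = None
    failures = []
    for j in range(1, max_j + 1):
        keep = {cid: ids[: min(j, len(ids))] for cid, ids in ranking.items()}
        restricted = data.restrict_poses(keep)
        try:
            params, weights = fit_lie_iterative(restricted, options)
            sdep = loo_sdep(restricted, options, n_poses=j)
        except (ConvergenceError, RankDeficientError, ValueError) as exc:
            failures.append((j, exc))
            logger.warning("pose count j=%d failed: %s", j, exc)
            continue
        logger.info("pose count j=%d: LOO SDEP %.4f kJ/mol", j, sdep)
        if best is None or sdep < best[0] - 1e-12:
            best = (sdep, j, params, weights, restricted)
    if best is None:
        raise ConvergenceError(
            f"all pose counts failed: {failures}", np.empty((0, 2))
        )
    sdep, j, params, weights, restricted = best
    preds = [
        _predict_with_params(params, j, options.constants, c.poses)
        for c in restricted
    ]
    resid = np.array(preds) - np.array([c.dg_obs for c in restricted])
    rmse = float(np.sqrt(np.mean(resid**2)))
    return LIEModel(
        params=params,
        n_poses=j,
        training_stats={"rmse": rmse, "sdep_cv": sdep},
        constants=options.constants,
        training_weights=weights,
    )
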