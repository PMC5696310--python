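"""Synthetic MD-like data with known ground truth.

Generates every input the other modules consume, without running docking or
MD: replicate-structured interaction-energy records following a known LIE
generating process, low-rank per-residue energy decompositions, planted
pose-coordinate clusters and fingerprint families.  All generators are pure
functions of their arguments and a seed.

The energy generator mirrors how the data arise in practice: a compound's
free-state ligand-water energies are simulated (with replicate noise), each
bound pose adds a pose-specific (dV_LJ, dV_Coul) shift, and the observed
binding free energy is the Boltzmann-weighted combination of the per-pose
LIE energies under the true coefficients, plus observation noise.  Default
magnitudes follow typical small-molecule MD energetics: LJ differences of
order -80 kJ/mol, electrostatic differences of order -30 kJ/mol, two
replicates per simulation, and kJ/mol-scale noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lie import (
    CalibrationSet,
    Compound,
    EnergyRecord,
    LIEParams,
    PoseDescriptor,
    ThermodynamicConstants,
    average_replicates,
    boltzmann_weights,
    pose_dg,
)

__all__ = [
    "GeneratorSpec",
    "gen_energy_dataset",
    "gen_residue_matrix",
    "gen_pose_cloud",
    "gen_fingerprints",
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic LIE data-generating process.

    ``poses_per_compound`` is either a fixed count or an inclusive
    ``(lo, hi)`` range sampled per compound.  Noise standard deviations are
    kJ/mol; ``replicate_noise_sd`` perturbs each replicate's time-averaged
    energies, ``observation_noise_sd`` perturbs the experimental dG.
    """

    n_compounds: int = 20
    poses_per_compound: int | tuple[int, int] = 1
    n_replicates: int = 2
    true_params: LIEParams = field(default_factory=lambda: LIEParams(0.5, 0.3))
    dv_lj_mean: float = -80.0
    dv_lj_sd: float = 25.0
    dv_coul_mean: float = -30.0
    dv_coul_sd: float = 15.0
    replicate_noise_sd: float = 0.0
    observation_noise_sd: float = 0.0
    n_residues: int = 20
    seed: int = 0
    constants: ThermodynamicConstants = field(default_factory=ThermodynamicConstants)

    def __post_init__(self):
        if self.n_compounds < 1 or self.n_replicates < 1 or self.n_residues < 1:
            raise ValueError("counts must be >= 1")
        if min(self.replicate_noise_sd, self.observation_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def _n_poses(self, rng: np.random.Generator) -> int:
        if isinstance(self.poses_per_compound, tuple):
            lo, hi = self.poses_per_compound
            return int(rng.integers(lo, hi + 1))
        return int(self.poses_per_compound)


def gen_energy_dataset(
    spec: GeneratorSpec,
) -> tuple[list[EnergyRecord], CalibrationSet, dict]:
    """Sample an energy dataset plus its calibration set and ground truth.

    Returns raw :class:`EnergyRecord` lists (bound and free, replicated),
    the :class:`CalibrationSet` obtained by replicate averaging with the
    noisy observed dG attached, and a ground-truth dict holding the
    generating coefficients, planted per-pose descriptors and dG values,
    Boltzmann weights and noiseless observations.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[EnergyRecord] = []
    truth_poses: dict[str, dict[str, tuple[float, float]]] = {}
    truth_dg: dict[str, dict[str, float]] = {}
    truth_weights: dict[str, dict[str, float]] = {}
    dg_noiseless: dict[str, float] = {}
    dg_obs: dict[str, float] = {}

    for ci in range(spec.n_compounds):
        cid = f"cpd{ci:03d}"
        n_poses = spec._n_poses(rng)
        # free-state ligand-water averages (typical solvation magnitudes)
        free_lj = rng.normal(-120.0, 10.0)
        free_coul = rng.normal(-150.0, 20.0)
        for rep in range(1, spec.n_replicates + 1):
            records.append(
                EnergyRecord(
                    cid,
                    None,
                    rep,
                    free_lj + rng.normal(0, spec.replicate_noise_sd),
                    free_coul + rng.normal(0, spec.replicate_noise_sd),
                )
            )
        planted = {}
        for pi in range(n_poses):
            pid = f"pose{pi:02d}"
            dv_lj = rng.normal(spec.dv_lj_mean, spec.dv_lj_sd)
            dv_coul = rng.normal(spec.dv_coul_mean, spec.dv_coul_sd)
            planted[pid] = (dv_lj, dv_coul)
            for rep in range(1, spec.n_replicates + 1):
                records.append(
                    EnergyRecord(
                        cid,
                        pid,
                        rep,
                        free_lj + dv_lj + rng.normal(0, spec.replicate_noise_sd),
                        free_coul + dv_coul + rng.normal(0, spec.replicate_noise_sd),
                    )
                )
        truth_poses[cid] = planted
        descriptors = [
            PoseDescriptor(cid, pid, *dv) for pid, dv in sorted(planted.items())
        ]
        dgs = [pose_dg(spec.true_params, p) for p in descriptors]
        w = boltzmann_weights(dgs, spec.constants)
        truth_dg[cid] = {p.pose_id: float(d) for p, d in zip(descriptors, dgs)}
        truth_weights[cid] = {
            p.pose_id: float(wi) for p, wi in zip(descriptors, w)
        }
        clean = float(np.dot(w, dgs))
        dg_noiseless[cid] = clean
        dg_obs[cid] = clean + rng.normal(0, spec.observation_noise_sd)

    descriptors = average_replicates(records)
    by_cpd: dict[str, list[PoseDescriptor]] = {}
    for d in descriptors:
        by_cpd.setdefault(d.compound_id, []).append(d)
    calib = CalibrationSet(
        [
            Compound(cid, dg_obs[cid], sorted(by_cpd[cid], key=lambda p: p.pose_id))
            for cid in sorted(by_cpd)
        ]
    )
    truth = {
        "params": spec.true_params,
        "pose_dv": truth_poses,
        "pose_dg": truth_dg,
        "weights": truth_weights,
        "dg_noiseless": dg_noiseless,
        "dg_obs": dg_obs,
    }
    return records, calib, truth


def gen_residue_matrix(
    spec: GeneratorSpec,
    totals_lj,
    totals_coul,
    noise_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Rank-2 per-residue energy decompositions plus noise.

    Two latent interaction profiles (e.g. a hydrophobic-pocket and a
    polar-contact pattern) are mixed per compound; each row is scaled so it
    sums to the compound's total interaction energy, then Gaussian noise of
    ``noise_sd`` kJ/mol is added.  Returns the LJ matrix, the Coulomb matrix
    and the residue id list.
    """
    totals_lj = np.asarray(totals_lj, dtype=float)
    totals_coul = np.asarray(totals_coul, dtype=float)
    if spec.n_residues < 2:
        raise ValueError("need >= 2 residues")
    rng = np.random.default_rng(spec.seed + 1)
    residue_ids = [f"RES{r + 1}" for r in range(spec.n_residues)]

    def one(totals: np.ndarray) -> np.ndarray:
        profiles = rng.dirichlet(np.ones(spec.n_residues), size=2)
        mix = rng.uniform(0, 1, size=len(totals))
        base = np.outer(mix, profiles[0]) + np.outer(1 - mix, profiles[1])
        mat = base * totals[:, None]
        return mat + rng.normal(0, noise_sd, size=mat.shape)

    return one(totals_lj), one(totals_coul), residue_ids


def gen_pose_cloud(
    k_planted: int,
    poses_per_cluster: int = 10,
    n_atoms: int = 20,
    cluster_sep: float = 8.0,
    jitter_sd: float = 0.3,
    seed: int = 0,
):
    """Planted pose clusters: rigid translations of one molecule plus jitter.

    Cluster centers are copies of a random base molecule translated along x
    in steps of ``cluster_sep`` Å, so the RMSD between any two centers is an
    exact multiple of ``cluster_sep``.  Each pose adds isotropic Gaussian
    jitter of ``jitter_sd`` Å per coordinate.  Returns the
    :class:`~poselie.clustering.PoseCloud` and the planted labels.
    """
    from .clustering import PoseCloud

    if cluster_sep <= 0:
        raise ValueError("cluster_sep must be positive")
    rng = np.random.default_rng(seed)
    base = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    coords, labels, ids = [], [], []
    for k in range(k_planted):
        center = base + np.array([k * cluster_sep, 0.0, 0.0])
        for p in range(poses_per_cluster):
            pose = center + rng.normal(0, jitter_sd, size=center.shape)
            coords.append(pose.ravel())
            labels.append(k)
            ids.append(f"c{k}_p{p}")
    return PoseCloud(ids, np.array(coords)), np.array(labels)


def gen_fingerprints(
    n: int,
    n_bits: int = 166,
    n_families: int = 2,
    mutation_rate: float = 0.1,
    n_outliers: int = 0,
    seed: int = 0,
):
    """Families of similar synthetic bit-set fingerprints plus optional outliers.

    Each family shares a random base bit-set; members toggle each bit of the
    universe with probability ``mutation_rate``.  Outliers (appended last)
    draw their bits from a disjoint index range, forcing best-neighbour
    Tanimoto 0 against every family member.
    """
    from .domain import Fingerprint

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.arange(1, n_bits + 1)
    bases = [
        set(universe[rng.random(n_bits) < 1 / 3]) or {1} for _ in range(n_families)
    ]
    fps = []
    n_members = n - n_outliers
    for i in range(n_members):
        base = bases[i % n_families]
        bits = set(base)
        for b in universe:
            if rng.random() < mutation_rate:
                bits.symmetric_difference_update({int(b)})
        fps.append(Fingerprint.from_bits(bits or {1}))
    alien = np.arange(n_bits + 1, 2 * n_bits + 1)
    for _ in range(n_outliers):
        bits = set(int(b) for b in alien[rng.random(n_bits) < 1 / 3]) or {
            int(alien[0])
        }
        fps.append(Fingerprint.from_bits(bits))
    return fps
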