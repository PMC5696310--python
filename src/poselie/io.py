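"""File formats: energy/residue tables, model archives, SDF and PDB input.

All tabular formats are plain delimited text with mandatory headers; the
model archive is JSON and round-trips losslessly.  Energies are kJ/mol
everywhere internally; the optional kcal/mol conversion happens only at the
SDF boundary.  RDKit and Biopython are imported lazily so the statistical
core works without a chemistry toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import (
    ADReference,
    EnergyDistributionRef,
    Fingerprint,
    ReliabilityReport,
    ResiduePCARef,
)
from .lie import (
    CalibrationSet,
    Compound,
    EnergyRecord,
    LIEModel,
    LIEParams,
    PoseDescriptor,
    ThermodynamicConstants,
)

SCHEMA_VERSION = 1
ENERGY_COLUMNS = ["compound_id", "pose_id", "replicate_id", "state", "v_lj", "v_coul"]
RESIDUE_COLUMNS = ["compound_id", "residue_id", "lj", "coul"]
KCAL_TO_KJ = 4.184
DEFAULT_DG_FIELD = "dG.obs"


class FormatError(ValueError):
    """A file does not match its documented schema."""


def _check_header(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        raise FormatError(
            f"{what}: expected columns {expected}, found {list(df.columns)}"
        )


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------


def read_energy_table(path) -> list[EnergyRecord]:
    """Read a delimited energy table into EnergyRecords.

    Schema: ``compound_id,pose_id,replicate_id,state,v_lj,v_coul`` with
    ``state`` in {bound, free}; free rows leave ``pose_id`` empty.
    """
    df = pd.read_csv(
        path, dtype={"compound_id": str, "pose_id": str},
        float_precision="round_trip",
    )
    _check_header(df, ENERGY_COLUMNS, f"energy table {path}")
    records = []
    for i, row in df.iterrows():
        state = row["state"]
        if state not in ("bound", "free"):
            raise FormatError(f"energy table row {i}: unknown state {state!r}")
        pose = None if state == "free" else row["pose_id"]
        if state == "bound" and (pose is None or pd.isna(pose) or pose == ""):
            raise FormatError(f"energy table row {i}: bound row without pose_id")
        records.append(
            EnergyRecord(
                str(row["compound_id"]),
                None if pose is None else str(pose),
                int(row["replicate_id"]),
                float(row["v_lj"]),
                float(row["v_coul"]),
            )
        )
    return records


def write_energy_table(records: list[EnergyRecord], path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "pose_id": "" if r.pose_id is None else r.pose_id,
            "replicate_id": r.replicate_id,
            "state": "free" if r.pose_id is None else "bound",
            "v_lj": r.v_lj,
            "v_coul": r.v_coul,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Residue tables
# ---------------------------------------------------------------------------


def read_residue_table(path):
    """Read per-residue weighted energies.

    Schema: ``compound_id,residue_id,lj,coul`` (one row per compound and
    residue).  Returns (lj matrix, coul matrix, compound_ids, residue_ids)
    with residues ordered by first appearance.
    """
    df = pd.read_csv(
        path, dtype={"compound_id": str, "residue_id": str},
        float_precision="round_trip",
    )
    _check_header(df, RESIDUE_COLUMNS, f"residue table {path}")
    compounds = list(dict.fromkeys(df["compound_id"]))
    residues = list(dict.fromkeys(df["residue_id"]))
    lj = df.pivot(index="compound_id", columns="residue_id", values="lj")
    coul = df.pivot(index="compound_id", columns="residue_id", values="coul")
    if lj.isna().any().any() or coul.isna().any().any():
        raise FormatError(f"residue table {path}: incomplete compound x residue grid")
    lj = lj.loc[compounds, residues].to_numpy(float)
    coul = coul.loc[compounds, residues].to_numpy(float)
    return lj, coul, compounds, residues


def write_residue_table(path, lj, coul, compound_ids, residue_ids) -> None:
    rows = []
    for i, cid in enumerate(compound_ids):
        for j, rid in enumerate(residue_ids):
            rows.append(
                {"compound_id": cid, "residue_id": rid, "lj": lj[i, j], "coul": coul[i, j]}
            )
    pd.DataFrame(rows, columns=RESIDUE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Model archive (JSON)
# ---------------------------------------------------------------------------


def _energy_ref_to_json(ref: EnergyDistributionRef) -> dict:
    return {
        "centroid": ref.centroid.tolist(),
        "covariance": ref.covariance.tolist(),
        "mahalanobis_cutoff": ref.mahalanobis_cutoff,
    }


def _energy_ref_from_json(d: dict) -> EnergyDistributionRef:
    return EnergyDistributionRef(
        np.array(d["centroid"]), np.array(d["covariance"]), d["mahalanobis_cutoff"]
    )


def _pca_ref_to_json(ref: ResiduePCARef | None):
    if ref is None:
        return None
    return {
        "residue_ids": ref.residue_ids,
        "mean_vector": ref.mean_vector.tolist(),
        "components": ref.components.tolist(),
        "component_variances": ref.component_variances.tolist(),
        "sd_cutoff": ref.sd_cutoff,
        "od_cutoff": ref.od_cutoff,
    }


def _pca_ref_from_json(d) -> ResiduePCARef | None:
    if d is None:
        return None
    return ResiduePCARef(
        residue_ids=list(d["residue_ids"]),
        mean_vector=np.array(d["mean_vector"]),
        components=np.array(d["components"]),
        component_variances=np.array(d["component_variances"]),
        sd_cutoff=d["sd_cutoff"],
        od_cutoff=d["od_cutoff"],
    )


def write_model(
    path, model: LIEModel, ad: ADReference | None = None, provenance: dict | None = None
) -> None:
    """Serialise a model (and optional AD reference) to a JSON archive."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "params": {
            "alpha": model.params.alpha,
            "beta": model.params.beta,
            "gamma": model.params.gamma,
            "include_gamma": model.params.include_gamma,
        },
        "n_poses": model.n_poses,
        "constants": {
            "k_b": model.constants.k_b,
            "temperature": model.constants.temperature,
        },
        "training_stats": model.training_stats,
        "training_weights": model.training_weights,
    }
    if ad is not None:
        doc["ad"] = {
            "dg_min": ad.dg_min,
            "dg_max": ad.dg_max,
            "ts_cutoff": ad.ts_cutoff,
            "energy_ref": _energy_ref_to_json(ad.energy_ref),
            "training_fingerprints": [sorted(fp.bits) for fp in ad.training_fingerprints],
            "lj_residue_ref": _pca_ref_to_json(ad.lj_residue_ref),
            "coul_residue_ref": _pca_ref_to_json(ad.coul_residue_ref),
        }
    if provenance is not None:
        doc["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> tuple[LIEModel, ADReference | None]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"model archive {path}: unsupported schema {doc.get('schema_version')!r}"
        )
    p = doc["params"]
    model = LIEModel(
        params=LIEParams(p["alpha"], p["beta"], p["gamma"], p["include_gamma"]),
        n_poses=doc["n_poses"],
        training_stats=doc["training_stats"],
        constants=ThermodynamicConstants(**doc["constants"]),
        training_weights=doc["training_weights"],
    )
    ad = None
    if "ad" in doc:
        a = doc["ad"]
        ad = ADReference(
            dg_min=a["dg_min"],
            dg_max=a["dg_max"],
            ts_cutoff=a["ts_cutoff"],
            energy_ref=_energy_ref_from_json(a["energy_ref"]),
            training_fingerprints=[
                Fingerprint.from_bits(b) for b in a["training_fingerprints"]
            ],
            lj_residue_ref=_pca_ref_from_json(a["lj_residue_ref"]),
            coul_residue_ref=_pca_ref_from_json(a["coul_residue_ref"]),
        )
    return model, ad


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


def write_predictions(path, rows: list[dict]) -> None:
    """Write the predictions CSV.

    Each row dict carries ``compound_id``, ``dg_pred``, ``n_poses_used`` and
    optionally a :class:`ReliabilityReport` under ``report``.
    """
    out = []
    for r in rows:
        rec = {
            "compound_id": r["compound_id"],
            "dg_pred": r["dg_pred"],
            "n_poses_used": r["n_poses_used"],
        }
        report: ReliabilityReport | None = r.get("report")
        if report is not None:
            rec.update(report.as_dict())
        out.append(rec)
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SDF input (RDKit)
# ---------------------------------------------------------------------------


@dataclass
class CompoundRecord:
    """One molecule read from an SDF file, with its data fields."""

    compound_id: str
    mol: object  # rdkit Mol
    properties: dict[str, str]
    dg_obs: float | None = None
    fingerprint: Fingerprint | None = None


def maccs_fingerprint(mol) -> Fingerprint:
    """166-key MACCS substructure fingerprint of an RDKit molecule."""
    from rdkit.Chem import MACCSkeys

    bv = MACCSkeys.GenMACCSKeys(mol)
    return Fingerprint.from_bits(b for b in bv.GetOnBits() if b > 0)


def read_sdf(
    path,
    dg_field: str = DEFAULT_DG_FIELD,
    require_dg: bool = True,
    kcal: bool = False,
    compute_fingerprints: bool = True,
) -> list[CompoundRecord]:
    """Read a V2000 multi-record SDF file.

    The compound id is the molecule title, or ``mol<i>`` if blank.  The
    experimental dG is parsed from ``dg_field`` (kJ/mol; pass ``kcal=True``
    to convert from kcal/mol).  In calibration mode (``require_dg``) records
    without the field raise an error naming the offenders; in prediction
    mode they are accepted with ``dg_obs=None``.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records = []
    missing = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"SDF {path}: malformed record at index {i}")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        cid = title.strip() or f"mol{i}"
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        dg = None
        if dg_field in props:
            try:
                dg = float(props[dg_field])
            except ValueError as exc:
                raise FormatError(
                    f"SDF {path}: record {cid!r} has non-numeric {dg_field!r}"
                ) from exc
            if kcal:
                dg *= KCAL_TO_KJ
        elif require_dg:
            missing.append(cid)
        fp = maccs_fingerprint(mol) if compute_fingerprints else None
        records.append(CompoundRecord(cid, mol, props, dg, fp))
    if missing:
        raise FormatError(
            f"SDF {path}: missing {dg_field!r} field for: " + ", ".join(missing)
        )
    return records


def write_sdf(path, records: list[CompoundRecord], dg_field: str = DEFAULT_DG_FIELD):
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    for r in records:
        mol = r.mol
        mol.SetProp("_Name", r.compound_id)
        for k, v in r.properties.items():
            mol.SetProp(k, str(v))
        if r.dg_obs is not None:
            mol.SetProp(dg_field, repr(r.dg_obs))
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Pose coordinate input
# ---------------------------------------------------------------------------


def read_pose_cloud(path):
    """Read docked poses into a PoseCloud.

    Accepts a multi-record SDF (one pose per record, consistent heavy-atom
    order) or a headerless delimited text matrix ``pose_id,x1,y1,z1,...``.
    """
    from .clustering import PoseCloud

    path = str(path)
    if path.lower().endswith(".sdf"):
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(path, removeHs=True, sanitize=True)
        ids, rows = [], []
        for i, mol in enumerate(supplier):
            if mol is None:
                raise FormatError(f"SDF {path}: malformed record at index {i}")
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            ids.append(title.strip() or f"pose{i}")
            conf = mol.GetConformer()
            coords = [
                conf.GetAtomPosition(a.GetIdx())
                for a in mol.GetAtoms()
                if a.GetAtomicNum() > 1
            ]
            rows.append(np.array([[p.x, p.y, p.z] for p in coords]).ravel())
        if len({r.size for r in rows}) > 1:
            raise FormatError(f"SDF {path}: inconsistent heavy-atom counts")
        return PoseCloud(ids, np.array(rows))

    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            ids.append(parts[0].strip())
            rows.append([float(x) for x in parts[1:]])
    if not ids:
        raise FormatError(f"pose matrix {path}: no rows")
    return PoseCloud(ids, np.array(rows))


def write_pose_cloud(path, cloud) -> None:
    with open(path, "w") as fh:
        for pid, row in zip(cloud.pose_ids, cloud.coords):
            fh.write(pid + "," + ",".join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# PDB input (Biopython) for binding-site residue selection
# ---------------------------------------------------------------------------


def read_pdb_residues(path) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates per residue, keyed ``<chain>:<resname><resseq>``.

    Hydrogens and waters are skipped; residues appear in file order.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("prot", str(path))
    out: dict[str, np.ndarray] = {}
    model = next(iter(structure))
    for chain in model:
        for res in chain:
            if res.id[0] != " ":  # heteroatoms/waters
                continue
            coords = [
                atom.coord for atom in res if atom.element not in ("H", "D")
            ]
            if coords:
                key = f"{chain.id}:{res.get_resname()}{res.id[1]}"
                out[key] = np.array(coords, dtype=float)
    return out


# ---------------------------------------------------------------------------
# Calibration-set assembly
# ---------------------------------------------------------------------------


def build_calibration_set(
    descriptors: list[PoseDescriptor], dg_obs: dict[str, float]
) -> CalibrationSet:
    """Join pose descriptors with observed dG values into a CalibrationSet."""
    by_cpd: dict[str, list[PoseDescriptor]] = {}
    for d in descriptors:
        by_cpd.setdefault(d.compound_id, []).append(d)
    missing = sorted(set(by_cpd) - set(dg_obs))
    if missing:
        raise ValueError("no observed dG for compound(s): " + ", ".join(missing))
    return CalibrationSet(
        [
            Compound(cid, float(dg_obs[cid]), sorted(ps, key=lambda p: p.pose_id))
            for cid, ps in sorted(by_cpd.items())
        ]
    )
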