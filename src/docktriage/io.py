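"""Plain-text readers and writers for all pipeline artifacts.

Everything is tab-separated with explicit headers.  Scores are written
at full precision so downstream ratio arithmetic is reproducible; any
rounding happens only in rendered report tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .scores import RECORD_COLUMNS, KnownInteractions, ScoreMatrix
from .synth import Pose

__all__ = ["read_records", "write_records", "read_drug_table",
           "write_drug_table", "read_known", "write_known",
           "read_matrix", "write_matrix", "read_pose_xyz",
           "write_pose_xyz", "pose_from_sdf", "load_config"]


def write_records(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


def read_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"protein_id": str,
                                                 "drug_id": str,
                                                 "structure_id": str,
                                                 "pocket_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"record file {path} missing columns: {missing}")
    return records


def write_drug_table(drugs: pd.DataFrame, path) -> None:
    drugs.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_drug_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"drug_id": str})
    if "drug_id" not in table.columns:
        raise DataError(f"drug table {path} lacks a 'drug_id' column")
    return table


def write_known(known: KnownInteractions, path) -> None:
    rows = sorted(known.pairs)
    out = pd.DataFrame(rows, columns=["protein_id", "drug_id"])
    if known.drug_status:
        out["status"] = [known.drug_status.get(d, "") for _, d in rows]
    out.to_csv(path, sep="\t", index=False)


def read_known(path) -> KnownInteractions:
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "drug_id"):
        if col not in table.columns:
            raise DataError(f"known-interaction file {path} lacks {col!r}")
    pairs = set(zip(table["protein_id"], table["drug_id"]))
    status = {}
    if "status" in table.columns:
        status = {d: s for d, s in zip(table["drug_id"], table["status"])
                  if isinstance(s, str) and s}
    return KnownInteractions(pairs=pairs, drug_status=status)


def write_matrix(matrix: ScoreMatrix, prefix) -> None:
    """Write <prefix>_icm.tsv, <prefix>_pmf.tsv, <prefix>_provenance.tsv."""
    prefix = Path(prefix)
    matrix.icm.to_csv(prefix.with_name(prefix.name + "_icm.tsv"), sep="\t",
                      float_format="%.6f", index_label="protein_id")
    matrix.pmf.to_csv(prefix.with_name(prefix.name + "_pmf.tsv"), sep="\t",
                      float_format="%.6f", index_label="protein_id")
    matrix.provenance.to_csv(
        prefix.with_name(prefix.name + "_provenance.tsv"), sep="\t",
        index=False)


def read_matrix(prefix) -> ScoreMatrix:
    prefix = Path(prefix)
    icm = pd.read_csv(prefix.with_name(prefix.name + "_icm.tsv"), sep="\t",
                      index_col="protein_id")
    pmf = pd.read_csv(prefix.with_name(prefix.name + "_pmf.tsv"), sep="\t",
                      index_col="protein_id")
    provenance = pd.read_csv(
        prefix.with_name(prefix.name + "_provenance.tsv"), sep="\t")
    return ScoreMatrix(icm=icm, pmf=pmf, provenance=provenance)


def write_pose_xyz(pose: Pose, path) -> None:
    """XYZ-like TSV: element, x, y, z (Å)."""
    out = pd.DataFrame({"element": pose.elements,
                        "x": pose.coords[:, 0],
                        "y": pose.coords[:, 1],
                        "z": pose.coords[:, 2]})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pose_xyz(path, pose_id: str = "") -> Pose:
    table = pd.read_csv(path, sep="\t")
    for col in ("element", "x", "y", "z"):
        if col not in table.columns:
            raise DataError(f"pose file {path} lacks column {col!r}")
    return Pose(elements=list(table["element"].astype(str)),
                coords=table[["x", "y", "z"]].to_numpy(float),
                id=pose_id or str(path))


def pose_from_sdf(path, pose_id: str = "") -> Pose:
    """First molecule of an SDF/MOL file as a Pose (requires RDKit)."""
    from rdkit import Chem  # deferred: chemistry input is optional

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise DataError(f"no readable molecule in {path}")
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x,
                        conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z]
                       for i in range(mol.GetNumAtoms())])
    elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
    return Pose(elements=elements, coords=coords, id=pose_id or str(path))


def load_config(path) -> dict:
    """Parse a YAML pipeline configuration file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise DataError(f"configuration file {path} must hold a mapping")
    return config
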