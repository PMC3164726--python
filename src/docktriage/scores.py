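"""Pocket-level record ingestion and the protein-drug score matrix.

A cross-docking run scores each drug against every pocket of every
structure of a protein, several replicates each.  The representative
score of a protein-drug pair is taken from the single best record — the
one with the minimum (most negative) icm score — and the pmf score
reported for the pair is the pmf of that same record, so the two numbers
always describe one physical pose.  Ties on icm are broken by pmf, then
lexicographically by pocket id, so aggregation is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "KnownInteractions", "MWFilterResult",
           "filter_drugs_by_mw", "aggregate_best", "reliable_proteins",
           "GOOD_SCORE_CUTOFF"]

#: default "good docking score" cutoff (icm units, more negative = better)
GOOD_SCORE_CUTOFF = -30.0

RECORD_COLUMNS = ["protein_id", "drug_id", "structure_id", "pocket_id",
                  "replicate", "icm_score", "pmf_score"]


@dataclass
class ScoreMatrix:
    """Best per-pair scores as dense protein x drug tables.

    ``icm`` and ``pmf`` are DataFrames indexed by protein id with drug-id
    columns; pairs never docked are NaN.  ``provenance`` is a long table
    (protein_id, drug_id, structure_id, pocket_id, replicate) recording
    which record supplied each pair's score.
    """

    icm: pd.DataFrame
    pmf: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.icm.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.icm.columns)

    @property
    def n_pairs(self) -> int:
        """Number of docked (present, non-NaN) protein-drug pairs."""
        return int(self.icm.notna().sum().sum())

    def pairs(self) -> set[tuple[str, str]]:
        """All docked (protein, drug) pairs."""
        stacked = self.icm.stack()
        return set(stacked.index.to_list())

    def to_long(self) -> pd.DataFrame:
        """Long-format (protein_id, drug_id, icm_score, pmf_score) table."""
        icm_long = self.icm.stack()
        pmf_long = self.pmf.stack()
        out = pd.DataFrame({"icm_score": icm_long, "pmf_score": pmf_long})
        out.index.names = ["protein_id", "drug_id"]
        return out.reset_index()

    def to_records(self) -> pd.DataFrame:
        """Re-expand to pocket-level record layout (one row per pair).

        Used for the idempotence of :func:`aggregate_best`.
        """
        prov = self.provenance.set_index(["protein_id", "drug_id"])
        long = self.to_long().set_index(["protein_id", "drug_id"])
        joined = long.join(prov, how="left").reset_index()
        return joined[RECORD_COLUMNS]


@dataclass
class KnownInteractions:
    """Annotated protein-drug interactions plus drug approval status."""

    pairs: set[tuple[str, str]]
    drug_status: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def orphans(self, matrix: ScoreMatrix) -> set[tuple[str, str]]:
        """Known pairs that reference a protein or drug absent from the matrix."""
        prots, drugs = set(matrix.proteins), set(matrix.drugs)
        return {(p, d) for p, d in self.pairs
                if p not in prots or d not in drugs}


@dataclass
class MWFilterResult:
    retained: list[str]
    excluded: pd.DataFrame  # columns: drug_id, molecular_weight, reason

    @property
    def retained_set(self) -> set[str]:
        return set(self.retained)


def filter_drugs_by_mw(drug_table: pd.DataFrame, lower: float = 100.0,
                       upper: float = 1000.0) -> MWFilterResult:
    """Drop drugs too small or too large for docking.

    A drug is retained when ``lower <= MW <= upper`` (bounds inclusive:
    the exclusion rule is MW strictly under ``lower`` or strictly over
    ``upper``).  Drugs with missing or non-numeric weights are excluded
    with a logged warning.
    """
    if "drug_id" not in drug_table.columns:
        raise DataError("drug table must have a 'drug_id' column")
    mw_col = ("molecular_weight" if "molecular_weight" in drug_table.columns
              else "mw" if "mw" in drug_table.columns else None)
    if mw_col is None:
        raise DataError("drug table must have a 'molecular_weight' (or 'mw') column")

    retained: list[str] = []
    excluded_rows: list[tuple[str, float, str]] = []
    mw_values = pd.to_numeric(drug_table[mw_col], errors="coerce")
    for drug_id, mw in zip(drug_table["drug_id"], mw_values):
        if not np.isfinite(mw):
            logger.warning("drug %s has a missing/non-numeric molecular "
                           "weight; excluded", drug_id)
            excluded_rows.append((drug_id, np.nan, "non-numeric weight"))
        elif mw < lower:
            excluded_rows.append((drug_id, mw, f"MW under {lower:g} g/mol"))
        elif mw > upper:
            excluded_rows.append((drug_id, mw, f"MW over {upper:g} g/mol"))
        else:
            retained.append(drug_id)
    excluded = pd.DataFrame(excluded_rows,
                            columns=["drug_id", "molecular_weight", "reason"])
    return MWFilterResult(retained=retained, excluded=excluded)


def aggregate_best(records: pd.DataFrame) -> ScoreMatrix:
    """Collapse pocket-level records to the best score per protein-drug pair.

    "Best" is the minimum icm score over all structures, pockets and
    replicates of the pair; the pmf reported for the pair comes from that
    same record.  Ties on icm fall back to the better (smaller) pmf, then
    to the lexicographically first pocket id and lowest replicate.
    Empty input yields an empty matrix.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"records missing columns: {missing}")
    if len(records) == 0:
        empty = pd.DataFrame(dtype=float)
        return ScoreMatrix(icm=empty, pmf=empty.copy(),
                           provenance=pd.DataFrame(columns=RECORD_COLUMNS[:5]))
    if not (np.isfinite(records["icm_score"]).all()
            and np.isfinite(records["pmf_score"]).all()):
        raise DataError("records contain non-finite scores")

    ordered = records.sort_values(
        ["protein_id", "drug_id", "icm_score", "pmf_score", "pocket_id",
         "structure_id", "replicate"],
        kind="mergesort")
    best = ordered.drop_duplicates(["protein_id", "drug_id"], keep="first")

    icm = best.pivot(index="protein_id", columns="drug_id",
                     values="icm_score").sort_index(axis=0).sort_index(axis=1)
    pmf = best.pivot(index="protein_id", columns="drug_id",
                     values="pmf_score").reindex(index=icm.index,
                                                 columns=icm.columns)
    provenance = (best[RECORD_COLUMNS[:5]]
                  .sort_values(["protein_id", "drug_id"], kind="mergesort")
                  .reset_index(drop=True))
    return ScoreMatrix(icm=icm, pmf=pmf, provenance=provenance)


def reliable_proteins(matrix: ScoreMatrix, known: KnownInteractions,
                      cutoff: float = GOOD_SCORE_CUTOFF) -> set[str]:
    """Proteins for which at least one annotated binder docks well.

    A protein is reliable-for-docking when at least one of its known
    pairs has best icm score <= ``cutoff``; such targets have
    demonstrated that their structure and pocket are tractable for the
    docking protocol.  Known pairs absent from the matrix count as
    not-docked and are logged.
    """
    out: set[str] = set()
    prots, drugs = set(matrix.proteins), set(matrix.drugs)
    for p, d in known.pairs:
        if p not in prots or d not in drugs:
            logger.info("known pair (%s, %s) absent from matrix; "
                        "counted as not docked", p, d)
            continue
        score = matrix.icm.at[p, d]
        if pd.notna(score) and score <= cutoff:
            out.add(p)
    return out
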