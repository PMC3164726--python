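"""Cognate-ligand classification and static pose RMSD evaluation.

When an annotated drug docks well, two follow-up questions decide how
much the result means: (1) was the protein structure crystallized with
the same or a chemically similar ligand (the easy, cognate-docking
scenario) or with a different ligand / no ligand at all, and (2) is the
docked geometry actually close to the crystallographic one?

Chemical similarity uses the Tanimoto *distance* between bit-vector
fingerprints (0 = identical molecules); a pair under the 0.54 default
threshold counts as similar, hence cognate.  Geometry uses the static
RMSD — docked and reference ligands are compared in the same coordinate
frame with no superposition, because the docking box already fixes the
frame.  Since atom numbering between a docked pose and a deposited
structure rarely agrees, the atom correspondence is recovered by an
element-constrained minimum-cost assignment on interatomic distances; a
comparison is only evaluable when at least 30% of the docked atoms can
be matched, and counts as a success at RMSD <= 2 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import DataError

__all__ = ["tanimoto_distance", "classify_docking_scenario",
           "PoseComparison", "rmsd_evaluate", "summarize_comparisons",
           "fp_to_hex", "fp_from_hex", "fingerprint_from_smiles",
           "SIMILARITY_THRESHOLD"]

#: Tanimoto distance below which two molecules count as similar
SIMILARITY_THRESHOLD = 0.54

UNLIGANDED = "unliganded"
LIGANDED_SIMILAR = "liganded-similar"
LIGANDED_DISSIMILAR = "liganded-dissimilar"


def _as_bits(fp) -> np.ndarray:
    arr = np.asarray(fp).astype(bool).ravel()
    if arr.size == 0:
        raise DataError("fingerprint must be non-empty")
    return arr


def tanimoto_distance(a, b) -> float:
    """1 - |A∩B| / |A∪B| over set bits; 0 means identical molecules.

    Two all-zero fingerprints (degenerate molecules) are defined to have
    distance 0, with a warning.
    """
    a, b = _as_bits(a), _as_bits(b)
    if a.size != b.size:
        raise DataError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("both fingerprints are all-zero; Tanimoto distance "
                      "defined as 0", stacklevel=2)
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return 1.0 - inter / union


def classify_docking_scenario(drug_fp, complexed_ligand_fp=None,
                              threshold: float = SIMILARITY_THRESHOLD) -> str:
    """Assign a known-interaction docking to its scenario.

    * no complexed ligand in the structure -> ``unliganded``;
    * Tanimoto distance strictly below ``threshold`` -> ``liganded-similar``
      (the cognate-docking scenario);
    * otherwise -> ``liganded-dissimilar``.
    """
    if not (0.0 < threshold < 1.0):
        raise DataError(f"threshold must lie in (0, 1), got {threshold}")
    if complexed_ligand_fp is None:
        return UNLIGANDED
    dist = tanimoto_distance(drug_fp, complexed_ligand_fp)
    return LIGANDED_SIMILAR if dist < threshold else LIGANDED_DISSIMILAR


# ---------------------------------------------------------------------------
# static RMSD with partial, element-constrained atom matching


@dataclass
class PoseComparison:
    """Outcome of one docked-vs-reference comparison.

    ``rmsd`` is in Å over the matched atoms and is None when nothing
    could be matched; ``success`` is defined only when ``evaluable``.
    """

    matched_fraction: float
    n_matched: int
    rmsd: float | None
    evaluable: bool
    success: bool | None


def rmsd_evaluate(docked, reference, min_match: float = 0.30,
                  success_cutoff: float = 2.0) -> PoseComparison:
    """Static RMSD between a docked pose and a reference pose.

    For every element present in both poses, atoms are paired by a
    minimum-cost assignment on squared interatomic distance; no
    superposition or re-fitting is applied.  The comparison is evaluable
    only when the matched fraction of docked atoms reaches ``min_match``,
    and successful when additionally RMSD <= ``success_cutoff``.  The
    result does not depend on atom input order.
    """
    if len(docked) == 0 or len(reference) == 0:
        raise DataError("poses must be non-empty")
    d_elems = np.asarray(docked.elements)
    r_elems = np.asarray(reference.elements)
    sq_sum = 0.0
    n_matched = 0
    for elem in sorted(set(d_elems) & set(r_elems)):
        d_idx = np.flatnonzero(d_elems == elem)
        r_idx = np.flatnonzero(r_elems == elem)
        cost = cdist(docked.coords[d_idx], reference.coords[r_idx],
                     "sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        sq_sum += float(cost[rows, cols].sum())
        n_matched += len(rows)
    matched_fraction = n_matched / len(docked)
    if n_matched == 0:
        return PoseComparison(matched_fraction=0.0, n_matched=0, rmsd=None,
                              evaluable=False, success=None)
    rmsd = float(np.sqrt(sq_sum / n_matched))
    evaluable = matched_fraction >= min_match
    success = (rmsd <= success_cutoff) if evaluable else None
    return PoseComparison(matched_fraction=matched_fraction,
                          n_matched=n_matched, rmsd=rmsd,
                          evaluable=evaluable, success=success)


def summarize_comparisons(comparisons: list[PoseComparison]) -> dict:
    """Counts of evaluable and successful comparisons plus the success rate.

    ``pct_success`` is the percentage of *evaluable* comparisons with
    RMSD under the success cutoff (None when nothing was evaluable).
    """
    n_evaluable = sum(1 for c in comparisons if c.evaluable)
    n_success = sum(1 for c in comparisons if c.evaluable and c.success)
    pct = 100.0 * n_success / n_evaluable if n_evaluable else None
    return {"n_total": len(comparisons), "n_evaluable": n_evaluable,
            "n_success": n_success, "pct_success": pct}


# ---------------------------------------------------------------------------
# fingerprint encoding and chemistry interface


def fp_to_hex(bits) -> str:
    """Encode a bit-vector as a hex string (big-endian, zero padded)."""
    arr = _as_bits(bits)
    return np.packbits(arr).tobytes().hex()


def fp_from_hex(text: str, length: int) -> np.ndarray:
    """Decode :func:`fp_to_hex` output back to a boolean vector."""
    raw = np.frombuffer(bytes.fromhex(text), dtype=np.uint8)
    bits = np.unpackbits(raw)[:length]
    if bits.size < length:
        raise DataError(f"hex string too short for length {length}")
    return bits.astype(bool)


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048) -> np.ndarray:
    """Path-based fingerprint of a molecule given as SMILES.

    Thin chemistry-toolkit adapter so the core similarity code can stay
    on plain bit-vectors; requires RDKit.
    """
    from rdkit import Chem  # deferred: chemistry input is optional

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"could not parse SMILES {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return np.array([fp.GetBit(i) for i in range(n_bits)], dtype=bool)
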