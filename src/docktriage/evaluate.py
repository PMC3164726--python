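"""PPV and enrichment-factor evaluation of predicted interaction sets.

The positive predictive value (PPV) of a predicted set is the percentage
of its pairs that are annotated known interactions.  The enrichment
factor versus random is the ratio of the set's known-interaction
fraction to the known fraction of the whole docked universe:

    EF = (k / n) / (K / N)

with k known among n predicted, out of K known among N docked pairs.
Ratios are always computed from the unrounded counts and only rounded
for display; chaining rounded intermediate values does not reproduce the
correct enrichment column of a report table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .prioritize import RankTable, ThresholdSpec, apply_threshold
from .scores import KnownInteractions, ScoreMatrix

__all__ = ["EvaluationResult", "evaluate", "evaluate_counts",
           "threshold_sweep", "make_comparison_table", "format_ppv",
           "format_ef"]


@dataclass
class EvaluationResult:
    """Counts and ratios for one predicted set.

    ``ppv`` is a percentage; ``ef_random`` is fold enrichment over
    drawing pairs at random from the docked universe.  Both are NaN when
    the predicted set is empty (not-applicable).
    """

    n_predicted: int
    n_known_in_predicted: int
    n_proteins_in_predicted: int
    ppv: float
    ef_random: float
    ef_baseline: float | None = None
    baseline_label: str | None = None


def evaluate_counts(n_predicted: int, n_known_in_predicted: int,
                    n_total_pairs: int, n_known_total: int,
                    n_proteins: int = 0) -> EvaluationResult:
    """Evaluation arithmetic from bare counts (no sets needed).

    Useful for re-deriving the PPV and enrichment columns of a report
    table from its printed count columns.
    """
    if n_known_total < 1:
        raise DataError("n_known_total must be >= 1")
    if not (n_total_pairs >= n_predicted >= 0):
        raise DataError("need n_total_pairs >= n_predicted >= 0")
    if not (0 <= n_known_in_predicted <= n_predicted):
        raise DataError("need 0 <= n_known_in_predicted <= n_predicted")
    if n_predicted == 0:
        return EvaluationResult(0, 0, 0, float("nan"), float("nan"))
    ppv = 100.0 * n_known_in_predicted / n_predicted
    ef = (n_known_in_predicted / n_predicted) / (n_known_total / n_total_pairs)
    return EvaluationResult(n_predicted=n_predicted,
                            n_known_in_predicted=n_known_in_predicted,
                            n_proteins_in_predicted=n_proteins,
                            ppv=ppv, ef_random=ef)


def evaluate(predicted: set[tuple[str, str]], known: KnownInteractions,
             n_total_pairs: int, n_known_total: int | None = None
             ) -> EvaluationResult:
    """Evaluate a predicted pair set against annotated interactions.

    ``n_total_pairs`` is the size of the docked universe (the number of
    pairs that were actually docked, not proteins x drugs when pairs are
    missing).  ``n_known_total`` defaults to the number of annotated
    pairs.
    """
    known_pairs = known.pairs if isinstance(known, KnownInteractions) else set(known)
    if n_known_total is None:
        n_known_total = len(known_pairs)
    n_predicted = len(predicted)
    n_known_in = len(predicted & known_pairs)
    n_proteins = len({p for p, _ in predicted})
    result = evaluate_counts(n_predicted, n_known_in, n_total_pairs,
                             n_known_total, n_proteins)
    return result


def format_ppv(ppv: float) -> str:
    """PPV displayed to one decimal place (percentage)."""
    return "n/a" if not math.isfinite(ppv) else f"{ppv:.1f}%"


def format_ef(ef: float) -> str:
    """Enrichment displayed to one decimal under 20, nearest integer from 20."""
    if not math.isfinite(ef):
        return "n/a"
    return f"{ef:.1f}" if ef < 20 else f"{ef:.0f}"


_SWEEP_FAMILIES = {
    "icm": lambda c: ThresholdSpec(icm_max=c),
    "pmf": lambda c: ThresholdSpec(pmf_max=c),
    "drug_rank": lambda c: ThresholdSpec(drug_rank_max=int(c)),
    "protein_rank": lambda c: ThresholdSpec(protein_rank_max=int(c)),
    "rank_sum": lambda c: ThresholdSpec(rank_sum_max=int(c)),
    "consensus": lambda c: ThresholdSpec(consensus_fraction=float(c)),
}


def threshold_sweep(matrix: ScoreMatrix, ranks: RankTable,
                    known: KnownInteractions, family: str,
                    cutoffs: list[float],
                    n_known_total: int | None = None
                    ) -> list[tuple[float, EvaluationResult]]:
    """Evaluate one threshold family over a list of cutoffs.

    When two cutoffs predict the same number of interactions, only the
    higher-PPV point is kept, so sweep curves are well defined.
    """
    if family not in _SWEEP_FAMILIES:
        raise ConfigError(f"unknown sweep family {family!r}; choose from "
                          f"{sorted(_SWEEP_FAMILIES)}")
    n_total = matrix.n_pairs
    points: list[tuple[float, EvaluationResult]] = []
    for cutoff in cutoffs:
        spec = _SWEEP_FAMILIES[family](cutoff)
        predicted = apply_threshold(spec, matrix, ranks, known)
        points.append((cutoff,
                       evaluate(predicted, known, n_total, n_known_total)))
    # same predicted-set size -> keep the higher PPV
    best_by_size: dict[int, tuple[float, EvaluationResult]] = {}
    order: list[int] = []
    for cutoff, res in points:
        size = res.n_predicted
        if size not in best_by_size:
            best_by_size[size] = (cutoff, res)
            order.append(size)
        else:
            _, existing = best_by_size[size]
            existing_ppv = -1.0 if math.isnan(existing.ppv) else existing.ppv
            new_ppv = -1.0 if math.isnan(res.ppv) else res.ppv
            if new_ppv > existing_ppv:
                best_by_size[size] = (cutoff, res)
    return [best_by_size[size] for size in order]


TABLE_COLUMNS = ["threshold", "n_predicted", "n_known_in_predicted",
                 "n_proteins", "ppv_pct", "ef_random"]


def make_comparison_table(matrix: ScoreMatrix, ranks: RankTable,
                          known: KnownInteractions,
                          specs: list[ThresholdSpec],
                          n_known_total: int | None = None) -> pd.DataFrame:
    """One evaluated row per threshold spec, sorted by increasing enrichment.

    Columns: threshold label, predicted / known-in-predicted / protein
    counts, PPV (%) and enrichment versus random, unrounded.
    """
    if not specs:
        raise ConfigError("specs must be non-empty")
    n_total = matrix.n_pairs
    rows = []
    for spec in specs:
        predicted = apply_threshold(spec, matrix, ranks, known)
        res = evaluate(predicted, known, n_total, n_known_total)
        rows.append((spec.describe(), res.n_predicted,
                     res.n_known_in_predicted, res.n_proteins_in_predicted,
                     res.ppv, res.ef_random))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return (table.sort_values("ef_random", kind="mergesort",
                              key=lambda s: s.fillna(-np.inf))
            .reset_index(drop=True))


def format_comparison_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering with display rounding applied."""
    shown = table.copy()
    shown["ppv_pct"] = shown["ppv_pct"].map(format_ppv)
    shown["ef_random"] = shown["ef_random"].map(format_ef)
    return shown.to_string(index=False)
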