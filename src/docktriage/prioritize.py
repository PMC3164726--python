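"""Selection machinery: consensus-score lines, ranks, threshold combinators.

The consensus score is a linear separator in the (icm, pmf) plane.  For a
score cloud — one protein's row of scores across all drugs, or one drug's
column across all proteins — a grid of lines ``pmf = slope*icm +
intercept`` is searched exhaustively; a point is *selected* when it lies
on or below the line (``pmf <= slope*icm + intercept``), which with
negative slopes keeps the bottom-left, jointly good-scoring region and
eliminates the dense top-right bulk of poor scores.  Among candidate
lines whose selected count comes closest to the requested fraction of the
cloud, the winner is the line that eliminates the *densest* cloud of
points, measured inside a trapezoidal region bounded by the line itself,
the best icm and pmf scores of the cloud, and the midpoints between the
worst icm/pmf scores and their means.

Mutual-specificity ranks complement the consensus: the drug-rank of a
pair is the rank of the drug among all drugs docked to that protein
(1 = best icm), and the protein-rank is the rank of the protein among
all targets the drug was docked to, computed under both the icm and the
pmf basis; a protein-rank criterion passes if met under either basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigError, DataError
from .scores import KnownInteractions, ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScoreCloud", "ConsensusLine", "RankTable", "ThresholdSpec",
           "consensus_select", "compute_ranks", "apply_threshold",
           "default_slope_grid", "default_intercept_grid",
           "cloud_for_protein", "cloud_for_drug"]

SLOPE_RANGE = (-40.0, -1.0)
INTERCEPT_RANGE = (-400.0, 0.0)


def default_slope_grid(step: float = 0.5) -> np.ndarray:
    """Slopes from -1 to -40 (pmf per icm unit)."""
    return -np.arange(1.0, 40.0 + 1e-9, step)


def default_intercept_grid(step: float = 2.0) -> np.ndarray:
    """Intercepts from 0 to -400 (pmf units)."""
    return -np.arange(0.0, 400.0 + 1e-9, step)


@dataclass
class ScoreCloud:
    """One protein's (or one drug's) icm/pmf score pairs.

    ``axis_label`` records the view: ``per-protein`` (points are drugs,
    the row view) or ``per-drug`` (points are proteins, the column view).
    """

    ids: list[str]
    icm: np.ndarray
    pmf: np.ndarray
    axis_label: str = "per-protein"

    def __post_init__(self) -> None:
        self.icm = np.asarray(self.icm, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if not (len(self.ids) == len(self.icm) == len(self.pmf)):
            raise DataError("cloud ids/icm/pmf length mismatch")
        if len(self.ids) == 0:
            raise DataError("a score cloud needs at least one point")
        if not (np.isfinite(self.icm).all() and np.isfinite(self.pmf).all()):
            raise DataError("cloud scores must be finite")

    def __len__(self) -> int:
        return len(self.ids)


def cloud_for_protein(matrix: ScoreMatrix, protein: str) -> ScoreCloud:
    """Row view: the protein's scores across all docked drugs."""
    if protein not in matrix.icm.index:
        raise DataError(f"protein {protein!r} not in matrix")
    icm_row = matrix.icm.loc[protein]
    mask = icm_row.notna()
    return ScoreCloud(ids=list(icm_row.index[mask]),
                      icm=icm_row[mask].to_numpy(),
                      pmf=matrix.pmf.loc[protein][mask].to_numpy(),
                      axis_label="per-protein")


def cloud_for_drug(matrix: ScoreMatrix, drug: str) -> ScoreCloud:
    """Column view: the drug's scores across all docked targets."""
    if drug not in matrix.icm.columns:
        raise DataError(f"drug {drug!r} not in matrix")
    icm_col = matrix.icm[drug]
    mask = icm_col.notna()
    return ScoreCloud(ids=list(icm_col.index[mask]),
                      icm=icm_col[mask].to_numpy(),
                      pmf=matrix.pmf[drug][mask].to_numpy(),
                      axis_label="per-drug")


@dataclass
class ConsensusLine:
    """A fitted consensus separator and the points it selects."""

    slope: float
    intercept: float
    target_fraction: float
    selected_ids: list[str]
    eliminated_density: float

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def _trapezoid_region(cloud: ScoreCloud, slope: float,
                      intercept: float) -> Polygon:
    """Clipped region used for the eliminated-point density.

    The axis-aligned rectangle spanning [best icm, midpoint(worst icm,
    mean icm)] x [best pmf, midpoint(worst pmf, mean pmf)], intersected
    with the eliminated half-plane pmf > slope*icm + intercept.
    """
    x0, x1 = float(cloud.icm.min()), float((cloud.icm.max() + cloud.icm.mean()) / 2)
    y0, y1 = float(cloud.pmf.min()), float((cloud.pmf.max() + cloud.pmf.mean()) / 2)
    if x1 <= x0 or y1 <= y0:
        return Polygon()
    rect = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    # half-plane as a generously padded polygon above the line
    pad = (x1 - x0) + (y1 - y0) + abs(intercept) + 1.0
    xa, xb = x0 - pad, x1 + pad
    ya, yb = slope * xa + intercept, slope * xb + intercept
    top = max(y1, ya, yb) + pad
    half = Polygon([(xa, ya), (xb, yb), (xb, top), (xa, top)])
    return rect.intersection(half)


def eliminated_density(cloud: ScoreCloud, slope: float,
                       intercept: float) -> float:
    """Density (points per unit score-area) of eliminated points inside
    the trapezoidal region; 0 when the region is degenerate."""
    region = _trapezoid_region(cloud, slope, intercept)
    if region.is_empty or region.area <= 0:
        return 0.0
    elim = cloud.pmf > slope * cloud.icm + intercept
    x0, x1 = float(cloud.icm.min()), float((cloud.icm.max() + cloud.icm.mean()) / 2)
    y0, y1 = float(cloud.pmf.min()), float((cloud.pmf.max() + cloud.pmf.mean()) / 2)
    inside = (elim & (cloud.icm >= x0) & (cloud.icm <= x1)
              & (cloud.pmf >= y0) & (cloud.pmf <= y1))
    return float(inside.sum()) / region.area


def consensus_select(cloud: ScoreCloud, fraction: float,
                     slope_grid: np.ndarray | None = None,
                     intercept_grid: np.ndarray | None = None) -> ConsensusLine:
    """Choose the consensus line selecting ~``fraction`` of the cloud.

    All slope x intercept grid combinations are enumerated.  Lines whose
    selected count is closest to ``round(fraction * N)`` are kept (count
    ties resolved toward the smaller, more stringent set); among those the
    line eliminating the densest cloud of points wins.  Remaining ties
    fall to grid order (steeper slopes and higher intercepts first),
    which makes the result deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction must lie in (0, 1], got {fraction}")
    n = len(cloud)
    if n == 0:
        raise DataError("cannot fit a consensus line to an empty cloud")
    slopes = np.asarray(default_slope_grid() if slope_grid is None
                        else slope_grid, dtype=float)
    intercepts = np.asarray(default_intercept_grid() if intercept_grid is None
                            else intercept_grid, dtype=float)
    if slopes.size == 0 or intercepts.size == 0:
        raise ConfigError("slope and intercept grids must be non-empty")

    target = int(round(fraction * n))
    if target < 1:
        warnings.warn(
            f"fraction {fraction} selects under one point of {n}; "
            "returning the line that selects the single best point",
            stacklevel=2)
        target = 1

    # counts[i, j] = number of points with pmf - slope_i*icm <= intercept_j
    counts = np.empty((slopes.size, intercepts.size), dtype=np.int64)
    for i, s in enumerate(slopes):
        t_sorted = np.sort(cloud.pmf - s * cloud.icm)
        counts[i] = np.searchsorted(t_sorted, intercepts, side="right")
    dists = np.abs(counts - target)
    cand = dists == dists.min()
    best_count = counts[cand].min()  # count distance ties -> smaller set
    cand &= counts == best_count

    best_line = None
    best_density = -np.inf
    if best_count == n:
        # full selection: nothing is eliminated, every candidate has
        # density 0; grid order decides
        i, j = np.argwhere(cand)[0]
        best_line, best_density = (float(slopes[i]), float(intercepts[j])), 0.0
    else:
        for i, j in np.argwhere(cand):  # grid order breaks density ties
            s, c = float(slopes[i]), float(intercepts[j])
            dens = eliminated_density(cloud, s, c)
            if dens > best_density:
                best_density = dens
                best_line = (s, c)

    s, c = best_line
    selected = cloud.pmf <= s * cloud.icm + c
    ids = [i for i, keep in zip(cloud.ids, selected) if keep]
    return ConsensusLine(slope=float(s), intercept=float(c),
                         target_fraction=fraction, selected_ids=ids,
                         eliminated_density=float(best_density))


# ---------------------------------------------------------------------------
# ranks


@dataclass
class RankTable:
    """Drug-ranks and dual-basis protein-ranks for every docked pair.

    All three tables share the matrix's protein x drug layout; missing
    pairs are NaN.  Within each protein the drug-ranks are a permutation
    of 1..n_docked_drugs; within each drug both protein-rank tables are
    permutations of 1..n_docked_proteins.  Ties break by ascending item
    id so ranks are deterministic.
    """

    drug_rank: pd.DataFrame
    protein_rank_icm: pd.DataFrame
    protein_rank_pmf: pd.DataFrame

    def protein_rank_best(self) -> pd.DataFrame:
        """Per-pair minimum of the icm- and pmf-based protein ranks."""
        return np.minimum(self.protein_rank_icm, self.protein_rank_pmf)


def _rank_along(values: pd.DataFrame, axis: int) -> pd.DataFrame:
    """Rank ascending along an axis, ties by ascending label, NaN-aware."""
    out = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    if axis == 1:
        for idx in values.index:
            row = values.loc[idx]
            present = row.notna()
            labels = row.index[present]
            order = np.lexsort((np.asarray(labels, dtype=object),
                                row[present].to_numpy()))
            ranks = np.empty(len(labels), dtype=float)
            ranks[order] = np.arange(1, len(labels) + 1)
            out.loc[idx, labels] = ranks
    else:
        out = _rank_along(values.T, axis=1).T
    return out


def compute_ranks(matrix: ScoreMatrix) -> RankTable:
    """Drug-ranks (icm basis) and protein-ranks (icm and pmf bases).

    Rank 1 is the most negative score.  The drug-rank uses the icm basis
    only; the protein-rank is computed under both score bases so that
    criteria can pass under either.
    """
    if matrix.icm.size == 0:
        raise DataError("cannot rank an empty matrix")
    return RankTable(
        drug_rank=_rank_along(matrix.icm, axis=1),
        protein_rank_icm=_rank_along(matrix.icm, axis=0),
        protein_rank_pmf=_rank_along(matrix.pmf, axis=0),
    )


# ---------------------------------------------------------------------------
# threshold combinators


@dataclass
class ThresholdSpec:
    """A conjunction of selection criteria defining a predicted set.

    Any combination of:

    * ``icm_max`` / ``pmf_max`` — plain score cutoffs (pair passes when
      score <= cutoff);
    * ``consensus_fraction`` — per-cloud consensus selection along
      ``consensus_axis`` ("per-protein" rows or "per-drug" columns);
    * ``drug_rank_max`` — drug-rank cutoff (icm basis);
    * ``protein_rank_max`` — protein-rank cutoff, satisfied under either
      score basis;
    * ``rank_sum_max`` — cutoff on drug_rank + protein_rank (mutual
      specificity);
    * ``known_cutoff`` — per-protein cutoff taken from that protein's
      known binders: ("best"|"worst", "icm"|"icm_pmf").  "worst icm" is
      the least negative icm among the protein's known binders; with
      "icm_pmf" both scores must pass their respective cutoffs.
    """

    icm_max: float | None = None
    pmf_max: float | None = None
    consensus_fraction: float | None = None
    consensus_axis: str = "per-protein"
    drug_rank_max: int | None = None
    protein_rank_max: int | None = None
    rank_sum_max: int | None = None
    known_cutoff: tuple[str, str] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not any(v is not None for v in (
                self.icm_max, self.pmf_max, self.consensus_fraction,
                self.drug_rank_max, self.protein_rank_max,
                self.rank_sum_max, self.known_cutoff)):
            raise ConfigError("a ThresholdSpec needs at least one criterion")
        if self.consensus_axis not in ("per-protein", "per-drug"):
            raise ConfigError(
                f"consensus_axis must be 'per-protein' or 'per-drug', "
                f"got {self.consensus_axis!r}")
        if self.known_cutoff is not None:
            which, basis = self.known_cutoff
            if which not in ("best", "worst") or basis not in ("icm", "icm_pmf"):
                raise ConfigError(
                    "known_cutoff must be (best|worst, icm|icm_pmf), "
                    f"got {self.known_cutoff!r}")

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = []
        if self.icm_max is not None:
            parts.append(f"icm<={self.icm_max:g}")
        if self.pmf_max is not None:
            parts.append(f"pmf<={self.pmf_max:g}")
        if self.consensus_fraction is not None:
            parts.append(f"consensus {100 * self.consensus_fraction:g}% "
                         f"({self.consensus_axis})")
        if self.drug_rank_max is not None:
            parts.append(f"drug_rank<={self.drug_rank_max}")
        if self.protein_rank_max is not None:
            parts.append(f"protein_rank<={self.protein_rank_max}")
        if self.rank_sum_max is not None:
            parts.append(f"rank_sum<={self.rank_sum_max}")
        if self.known_cutoff is not None:
            parts.append(f"known-binder {self.known_cutoff[0]} "
                         f"{self.known_cutoff[1]} cutoff")
        return " & ".join(parts)


def _consensus_mask(matrix: ScoreMatrix, fraction: float, axis: str,
                    slope_grid, intercept_grid) -> pd.DataFrame:
    mask = pd.DataFrame(False, index=matrix.icm.index,
                        columns=matrix.icm.columns)
    if axis == "per-protein":
        for protein in matrix.proteins:
            cloud = cloud_for_protein(matrix, protein)
            line = consensus_select(cloud, fraction, slope_grid, intercept_grid)
            mask.loc[protein, line.selected_ids] = True
    else:
        for drug in matrix.drugs:
            cloud = cloud_for_drug(matrix, drug)
            line = consensus_select(cloud, fraction, slope_grid, intercept_grid)
            mask.loc[line.selected_ids, drug] = True
    return mask


def _known_cutoff_mask(spec_kc: tuple[str, str], matrix: ScoreMatrix,
                       known: KnownInteractions) -> pd.DataFrame:
    which, basis = spec_kc
    agg = np.nanmin if which == "best" else np.nanmax
    mask = pd.DataFrame(False, index=matrix.icm.index,
                        columns=matrix.icm.columns)
    by_protein: dict[str, list[str]] = {}
    drugs = set(matrix.drugs)
    for p, d in known.pairs:
        if p in matrix.icm.index and d in drugs:
            by_protein.setdefault(p, []).append(d)
    for protein in matrix.proteins:
        binders = by_protein.get(protein, [])
        icm_scores = [matrix.icm.at[protein, d] for d in binders
                      if pd.notna(matrix.icm.at[protein, d])]
        if not icm_scores:
            logger.info("protein %s has no docked known binders; contributes "
                        "no predictions under the known-binder cutoff", protein)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            icm_cut = float(agg(icm_scores))
        passes = matrix.icm.loc[protein] <= icm_cut
        if basis == "icm_pmf":
            pmf_scores = [matrix.pmf.at[protein, d] for d in binders
                          if pd.notna(matrix.pmf.at[protein, d])]
            pmf_cut = float(agg(pmf_scores))
            passes &= matrix.pmf.loc[protein] <= pmf_cut
        mask.loc[protein] = passes.fillna(False)
    return mask


def apply_threshold(spec: ThresholdSpec, matrix: ScoreMatrix,
                    ranks: RankTable | None = None,
                    known: KnownInteractions | None = None,
                    slope_grid=None,
                    intercept_grid=None) -> set[tuple[str, str]]:
    """All docked pairs satisfying every criterion of ``spec``."""
    needs_ranks = any(v is not None for v in (spec.drug_rank_max,
                                              spec.protein_rank_max,
                                              spec.rank_sum_max))
    if needs_ranks and ranks is None:
        raise DataError("spec uses rank criteria but no RankTable was given")
    if spec.known_cutoff is not None and known is None:
        raise DataError("spec uses a known-binder cutoff but no "
                        "KnownInteractions was given")

    mask = matrix.icm.notna()
    if spec.icm_max is not None:
        mask &= (matrix.icm <= spec.icm_max).fillna(False)
    if spec.pmf_max is not None:
        mask &= (matrix.pmf <= spec.pmf_max).fillna(False)
    if spec.drug_rank_max is not None:
        mask &= (ranks.drug_rank <= spec.drug_rank_max).fillna(False)
    if spec.protein_rank_max is not None:
        mask &= (ranks.protein_rank_best() <= spec.protein_rank_max).fillna(False)
    if spec.rank_sum_max is not None:
        rank_sum = ranks.drug_rank + ranks.protein_rank_best()
        mask &= (rank_sum <= spec.rank_sum_max).fillna(False)
    if spec.consensus_fraction is not None:
        mask &= _consensus_mask(matrix, spec.consensus_fraction,
                                spec.consensus_axis, slope_grid,
                                intercept_grid)
    if spec.known_cutoff is not None:
        mask &= _known_cutoff_mask(spec.known_cutoff, matrix, known)

    stacked = mask.stack()
    return set(stacked.index[stacked].to_list())
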