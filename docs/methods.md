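# Methods

## Problem setting

Large-scale cross-docking scores every drug in a library against every
binding pocket of every available structure of every protein target,
producing pocket-level records `(protein, structure, pocket, drug,
replicate, icm, pmf)`. Both scores are dimensionless with more negative
meaning better: the icm score is an empirical energetics-based docking
score, the pmf (potential of mean force) score a statistical score
comparing the docked pose's interatomic contacts to known complexes.
Docking at this scale has a high false-positive rate, so the scientific
content of this package is the *triage*: turning the raw score matrix
into a small predicted-interaction set enriched for real binders, and
quantifying that enrichment.

## Score aggregation

The representative score of a protein–drug pair is the record with the
minimum icm score over all structures, pockets and replicates of the
pair; the pmf reported for the pair is the pmf of that same record, so
the two numbers always describe one physical pose. The aggregation basis
is the icm score (the primary score of the docking protocol); pmf-based
aggregation would mix poses. Ties on icm break by better pmf, then
lexicographic pocket id, then replicate, making aggregation
deterministic and idempotent. Pairs never docked are absent (NaN), not
imputed, and every set size downstream counts present pairs only.

The molecular-weight filter removes drugs strictly under 100 or over
1000 g/mol before aggregation (bounds themselves are retained). A
protein is *reliable for docking* when at least one of its annotated
binders reaches the good-score cutoff, icm ≤ −30 by default
(configurable); only for such targets has the protocol demonstrated it
can rank a true binder well.

## Consensus score

For a score cloud — one protein's row across drugs, or one drug's
column across targets — the consensus threshold is the line
`pmf = a·icm + b` selecting points with `pmf ≤ a·icm + b`. With
negative slopes this keeps the bottom-left (jointly good) region. The
grid `a ∈ [−40, −1]` step 0.5, `b ∈ [−400, 0]` step 2 is enumerated
exhaustively (the ranges are part of the method; the steps are a
resolution choice — fine enough that any target count on a 10³–10⁴
point cloud is attainable, coarse enough for exhaustive search to stay
interactive; both grids are parameters).

Line choice: keep the lines whose selected count is closest to
`round(fraction·N)`; resolve count-distance ties toward the smaller
(more stringent) set; among the remainder pick the line that eliminates
the densest cloud of points. The density region is the axis-aligned
rectangle `[best icm, midpoint(worst icm, mean icm)] × [best pmf,
midpoint(worst pmf, mean pmf)]` clipped by the eliminated half-plane
(`pmf` above the line); density is eliminated points inside that region
divided by its area (computed with shapely). This rectangle-plus-line
reading is one literal interpretation of a "trapezoidal area delineated
by the line, the best scores, and the worst-score/mean midpoints"; the
exact geometry is not otherwise recoverable, and the choice is
documented here as a design decision. Remaining density ties (typically
exact, e.g. all-zero when no points fall in the region) resolve by grid
order, so the fit is deterministic. A fraction selecting under one point
warns and selects the single best point; an empty cloud is an error.

Consensus criteria inside a threshold spec are evaluated per cloud
along the stated axis (per-protein by default, per-drug for the
drug-centric view); a global fraction across all pairs is deliberately
not offered, since the per-cloud form is what makes the criterion
independent of how promiscuous each target is.

## Ranks and threshold combinators

Within each protein, drugs are ranked by ascending icm (rank 1 = most
negative); within each drug, proteins are ranked twice, by icm and by
pmf. A protein-rank criterion passes when satisfied under *either*
basis (`min(rank_icm, rank_pmf)`); the drug-rank uses the icm basis
only. Ties break by ascending item id, so every rank table is an exact
permutation and reproducible across platforms.

A threshold specification is a conjunction of any of: plain icm/pmf
cutoffs, a consensus fraction, drug-rank / protein-rank / rank-sum
cutoffs, and per-protein known-binder score cutoffs ("worst icm" = the
least negative icm among the protein's docked known binders, "best" the
most negative; the icm+pmf variant requires both scores to pass their
respective cutoffs). A protein with no docked known binder contributes
no predictions under a known-binder criterion. Tightening any single
criterion can only shrink the predicted set (tested property).

## Evaluation

For a predicted set of n pairs with k known interactions out of N
docked pairs holding K known ones: `PPV = 100·k/n` (percent) and
`EF = (k/n)/(K/N)` (fold over random selection). N is the number of
docked pairs, not proteins × drugs, when pairs are missing. Ratios are
computed unrounded and rounded only for display — PPV to one decimal,
EF to one decimal below 20 and to the nearest integer from 20 up. The
unrounded chain matters: 22 known of 45 predicted against a
1,164,492-pair universe with 1116 known gives EF 510.1 → "510", whereas
chaining the printed PPV roundings would give 488. In threshold sweeps,
when two settings predict the same number of interactions only the
higher-PPV point is emitted. Comparison tables carry one row per spec,
sorted by increasing enrichment.

## Cognate classification and static RMSD

Molecular similarity uses the Tanimoto *distance* on bit-vector
fingerprints, `1 − |A∩B|/|A∪B|` (0 = identical); a docked drug whose
structure's complexed ligand is within distance 0.54 (strictly below)
is a cognate docking, a structure with no ligand is unliganded, and the
rest are liganded-dissimilar. The 0.54 default is a conventional
similarity cutoff and is configurable; the fingerprint type is abstract
(any consistent bit-vector), with an optional RDKit path-based
fingerprint adapter for SMILES input. Two all-zero fingerprints get
distance 0 with a warning.

Pose quality uses *static* RMSD: docked and reference coordinates are
compared in the same frame with no superposition, since the receptor
frame is shared. Because atom numbering differs between docked poses
and deposited ligands, the correspondence is recovered per element by a
minimum-cost linear assignment on squared interatomic distances
(scipy); the comparison is evaluable when ≥ 30% of docked atoms are
matched and a success at RMSD ≤ 2 Å. Assignment is order-free, so the
result is invariant to atom input order. Symmetry-aware RMSD (e.g.
flipped poses of partly symmetric ligands such as NAD scoring high RMSD
despite a correctly placed core) is out of scope and not special-cased.

## Synthetic landscapes

The generator emulates the statistical structure the triage relies on:

* pocket-level (icm, pmf) pairs from a bivariate normal (default
  correlation 0.6; means −14/−90, sds 5/35 score units) with a
  per-protein location offset of sd 4 ("promiscuity", applied to both
  scores with the pmf offset scaled by the sd ratio), clamped at 0
  because docking scores are reported as non-positive;
* a full factorial of proteins × pockets (3, grouped two per structure)
  × drugs × replicates (2);
* planted known binders (default 5 per protein, optionally
  negative-binomial across proteins) of which a Bernoulli
  `dockable_fraction` receive an additive pair-level shift toward
  better scores (applied to every pocket/replicate, so best-score
  aggregation preserves the plant); ground-truth flags are kept;
* drug properties: uniform molecular weights over (90, 1040) g/mol so
  ~5% violate the 100–1000 filter, approved status at probability 0.28,
  and random fingerprints.

The defaults `dockable_fraction = 0.32`, `binder_shift_icm = −16` were
frozen by a pilot simulation (10,000 known pairs) so that after
aggregation ~31% of known pairs reach icm ≤ −30, matching the success
rate observed when docking annotated binders against rigid receptors;
this single figure of merit is the generator's calibration target.

What the generator does *not* emulate: real chemistry (fingerprints
carry no structural similarity between related drugs), non-Gaussian
score tails, correlations between a drug's scores across related
targets, or protein-family structure. Tests passing on these landscapes
therefore establish the correctness and internal behavior of the triage
machinery — recovery of planted signal, exhaustive-search equivalence,
arithmetic — not the docking accuracy obtainable on any real screen.
The distributional form itself (bivariate normal with offsets) is a
modeling choice motivated by the dense elliptical clouds with sparse
good-score tails seen in real score plots.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problems chosen to
exercise every code path with comfortable statistics: 30 proteins × 500
drugs × 20 seeds for the planted-binder recovery comparison (PPV of
{consensus 1% AND protein-rank ≤ 5} vs {icm ≤ −30}, shift of 2
background sd, 80% dockable), 10,000 known pairs for the calibration
check (±3-point band), 50 clouds of ≤ 200 points for the
consensus-vs-enumeration oracle (on a coarser 1 × 5 grid, still
exhaustive), and 100 random matrices for rank verification. Oracles in
the tests are deliberately naive — per-line loops, `sorted()` ranking,
numerical integration for the density area — and share no code with the
implementation.

Degenerate inputs: empty record sets aggregate to an empty matrix;
empty prediction sets report PPV/EF as not-applicable rather than 0;
degenerate density rectangles (all points identical in one coordinate)
give density 0; known pairs absent from the matrix count as not docked
and are logged, never errors.

## Known limitations

* The consensus separator is linear by design; no learned separator is
  provided (the method is meant to work for targets with one or zero
  known binders, where nothing could be trained).
* GraphML round-trips preserve all node/edge attributes; SIF is lossy
  by nature and relies on its sidecar attribute tables.
* Enrichment factors are reported without significance testing.
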