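"""Independent brute-force oracles used to check the selection machinery.

Deliberately naive: plain loops, sorted() ranking, and numerical
integration for the eliminated-density area, sharing no code with the
implementation they verify.
"""

import numpy as np


def oracle_region_area(icm, pmf, slope, intercept, n_grid=4001):
    """Area of the density region by 1-D numerical integration.

    Region: rectangle [min icm, mid(max icm, mean icm)] x [min pmf,
    mid(max pmf, mean pmf)] restricted to points strictly above the line.
    """
    x0, x1 = min(icm), (max(icm) + np.mean(icm)) / 2
    y0, y1 = min(pmf), (max(pmf) + np.mean(pmf)) / 2
    if x1 <= x0 or y1 <= y0:
        return 0.0
    xs = np.linspace(x0, x1, n_grid)
    line = np.clip(slope * xs + intercept, y0, y1)
    return float(np.trapezoid(y1 - line, xs))


def oracle_density(icm, pmf, slope, intercept):
    icm, pmf = np.asarray(icm), np.asarray(pmf)
    area = oracle_region_area(icm, pmf, slope, intercept)
    if area <= 0:
        return 0.0
    x0, x1 = icm.min(), (icm.max() + icm.mean()) / 2
    y0, y1 = pmf.min(), (pmf.max() + pmf.mean()) / 2
    inside = ((pmf > slope * icm + intercept)
              & (icm >= x0) & (icm <= x1) & (pmf >= y0) & (pmf <= y1))
    return inside.sum() / area


def oracle_consensus(ids, icm, pmf, fraction, slopes, intercepts):
    """Exhaustive enumeration of the slope x intercept grid.

    Returns (slope, intercept, selected id set, density) chosen with the
    same rules as the implementation: selected count closest to
    round(fraction*N), count ties toward the smaller set, then maximal
    eliminated density, then grid order.
    """
    icm, pmf = np.asarray(icm, float), np.asarray(pmf, float)
    n = len(ids)
    target = max(1, int(round(fraction * n)))
    enumerated = []
    for s in slopes:
        for c in intercepts:
            count = int((pmf <= s * icm + c).sum())
            enumerated.append((s, c, count))
    best_dist = min(abs(count - target) for _, _, count in enumerated)
    cands = [e for e in enumerated if abs(e[2] - target) == best_dist]
    smallest = min(count for _, _, count in cands)
    cands = [e for e in cands if e[2] == smallest]
    best = None
    best_density = -np.inf
    for s, c, count in cands:  # grid order
        dens = oracle_density(icm, pmf, s, c)
        if dens > best_density:
            best_density = dens
            best = (s, c)
    s, c = best
    selected = {i for i, keep in zip(ids, pmf <= s * icm + c) if keep}
    return s, c, selected, best_density


def oracle_ranks(matrix_df, axis):
    """Brute-force sorted() ranking, ascending score then ascending label."""
    out = {}
    if axis == "row":
        for protein in matrix_df.index:
            row = matrix_df.loc[protein].dropna()
            order = sorted(row.index, key=lambda d: (row[d], d))
            for r, d in enumerate(order, start=1):
                out[(protein, d)] = r
    else:
        for drug in matrix_df.columns:
            col = matrix_df[drug].dropna()
            order = sorted(col.index, key=lambda p: (col[p], p))
            for r, p in enumerate(order, start=1):
                out[(drug, p)] = r
    return out
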