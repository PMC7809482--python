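"""Rank-based group comparisons and expansion/seeding capacity arithmetic.

The figure-level statistics of the platform validation are nonparametric:
Mann-Whitney U for two-group comparisons (seeding homogeneity CVs,
automated vs manual splits) and Kruskal-Wallis followed by Dunn's multiple
comparison test across organoid lines.  They are implemented from the rank
formulas with midrank tie handling; an exact enumeration branch covers the
small group sizes (n = 3-12) the figure panels use.

The capacity calculator turns per-plate cell yields into the number of
384-well assay plates a production run can seed, and the seeding helper
converts a suspension concentration and dispense volume into cells per
well.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, floor
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata


@dataclass(frozen=True)
class GroupTable:
    """Named groups of scalar measurements for rank statistics."""

    groups: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {str(k): np.asarray(v, float).ravel() for k, v in self.groups.items()}
        if len(clean) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in clean.items():
            if vals.size < 1:
                raise ValueError(f"group {name!r} is empty")
        object.__setattr__(self, "groups", clean)

    @property
    def names(self) -> list[str]:
        return list(self.groups)


def _as_table(table) -> GroupTable:
    if isinstance(table, GroupTable):
        return table
    return GroupTable(dict(table))


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(group_a, group_b, exact_limit: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)`` under midrank ties.  For
    tie-free samples with ``n_a + n_b <= exact_limit`` the p-value is exact,
    by full enumeration of all label assignments (the null distribution of
    ``min(U_a, U_b)``); otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(group_a, float).ravel()
    b = np.asarray(group_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u = min(u_a, u_b)

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and na + nb <= exact_limit:
        # exact: under H0 every choice of the n_a positions among the sorted
        # pooled values is equally likely
        order_ranks = np.arange(1, na + nb + 1)
        total = comb(na + nb, na)
        count = 0
        offset = na * (na + 1) / 2.0
        for pos in combinations(range(na + nb), na):
            ua = order_ranks[list(pos)].sum() - offset
            if min(ua, na * nb - ua) <= u + 1e-12:
                count += 1
        return float(u), count / total

    n = na + nb
    mu = na * nb / 2.0
    var = (na * nb / 12.0) * ((n + 1) - _tie_sum(pooled) / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0  # every observation identical
    z = (u - mu + 0.5) / np.sqrt(var)  # U <= mu by construction
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return float(u), p


def kruskal_wallis(table) -> tuple[float, int, float]:
    """Kruskal-Wallis H test over named groups, with midrank tie correction.

    Returns ``(H, df, p)`` where ``df = k - 1`` and p comes from the
    chi-square approximation.  When every observation is identical H is
    defined as 0 and p as 1.
    """
    table = _as_table(table)
    groups = list(table.groups.values())
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g, sz in zip(groups, sizes):
        r = ranks[start:start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_sum(pooled) / (n ** 3 - n)
    df = len(groups) - 1
    if correction <= 0:
        return 0.0, df, 1.0
    h /= correction
    return float(h), df, float(chi2.sf(h, df))


def dunn_posthoc(table, adjustment: str = "bonferroni") -> list[dict]:
    """Dunn's multiple-comparison z tests after Kruskal-Wallis.

    For each group pair, ``z = (mean_rank_i - mean_rank_j) /
    sqrt((N(N+1)/12 - tie_term) (1/n_i + 1/n_j))`` with the tie term
    ``sum(t^3 - t) / (12 (N - 1))``; two-sided p from the standard normal.
    Bonferroni adjustment multiplies by the number of pairs, capped at 1.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    table = _as_table(table)
    names = table.names
    groups = [table.groups[n] for n in names]
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    var_base = n * (n + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (n - 1))
    m = len(names) * (len(names) - 1) // 2
    results = []
    for i, j in combinations(range(len(names)), 2):
        se2 = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        p_raw = min(1.0, 2.0 * float(norm.sf(abs(z))))
        p_adj = min(1.0, p_raw * m) if adjustment == "bonferroni" else p_raw
        results.append({"group_a": names[i], "group_b": names[j],
                        "z": float(z), "p_raw": p_raw, "p_adjusted": p_adj})
    return results


# ---------------------------------------------------------------------------
# capacity and seeding arithmetic


@dataclass(frozen=True)
class CapacityPlan:
    """How many full assay plates a production run of source plates seeds."""

    n_source_plates: int
    yield_per_plate: float
    wells_per_assay_plate: int
    cells_per_assay_well: int
    n_assay_plates: int


def assay_capacity(n_source_plates: int, yield_per_plate: float,
                   wells_per_assay_plate: int = 384,
                   cells_per_assay_well: int = 20_000) -> CapacityPlan:
    """Number of complete assay plates the harvested cells can seed.

    Floor division: partial plates are unusable.  The default assay format
    is a 384-well plate at 20,000 cells per well (7.68e6 cells per plate).
    """
    if n_source_plates < 0 or int(n_source_plates) != n_source_plates:
        raise ValueError("n_source_plates must be a non-negative integer")
    if yield_per_plate <= 0 or wells_per_assay_plate <= 0 or cells_per_assay_well <= 0:
        raise ValueError("yields, wells and cells per well must be positive")
    total = n_source_plates * yield_per_plate
    per_plate = wells_per_assay_plate * cells_per_assay_well
    return CapacityPlan(
        n_source_plates=int(n_source_plates),
        yield_per_plate=float(yield_per_plate),
        wells_per_assay_plate=int(wells_per_assay_plate),
        cells_per_assay_well=int(cells_per_assay_well),
        n_assay_plates=int(floor(total / per_plate)),
    )


def seeding_cells_per_well(concentration: float, volume_ul: float) -> int:
    """Cells dispensed per well: concentration (cells/ml) x volume (µl).

    30,000 cells/ml at 100 µl per well gives the 3,000 cells used to seed
    one organoid.  Rounded to the nearest integer (ties up).
    """
    if concentration < 0 or volume_ul < 0:
        raise ValueError("concentration and volume must be non-negative")
    return int(floor(concentration * volume_ul / 1000.0 + 0.5))
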