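"""Group statistics: class totals, exact Mann-Whitney tests, direction calls.

The study design is two groups (HFD steatosis controls vs STAM NASH mice)
crossed with two ages (8 and 12 weeks), n = 5 per cell. At these sample
sizes the exact permutation null of the Mann-Whitney U statistic is cheap to
enumerate, so two-sided p-values are computed by full enumeration of all
C(m+n, n) group labelings of the pooled values, with mid-ranks for ties
inside the enumeration. A tie-corrected normal approximation is used only
when the enumeration would exceed a size cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .catalogue import LipidCatalogue

#: above this many labelings, fall back to the normal approximation
ENUMERATION_CAP = 50_000

Cell = tuple[str, int]  # (group, age_weeks)


@dataclass(frozen=True)
class Contrast:
    """A two-cell comparison; direction calls are test vs reference."""

    test: Cell
    ref: Cell

    @property
    def name(self) -> str:
        return f"{self.test[0]}-{self.test[1]}w_vs_{self.ref[0]}-{self.ref[1]}w"


#: the comparisons reported for this design
DEFAULT_CONTRASTS = (
    Contrast(test=("STAM", 8), ref=("HFD", 8)),     # steatosis vs NASH
    Contrast(test=("STAM", 12), ref=("HFD", 12)),
    Contrast(test=("STAM", 12), ref=("STAM", 8)),   # NASH -> fibrosis
    Contrast(test=("HFD", 12), ref=("HFD", 8)),
)


def samples_in_cell(sheet: pd.DataFrame, cell: Cell) -> list[str]:
    group, age = cell
    mask = (sheet["group"] == group) & (sheet["age_weeks"] == age)
    return list(sheet.index[mask])


# ---------------------------------------------------------------------------
# exact Mann-Whitney

@lru_cache(maxsize=32)
def _labeling_matrix(n_total: int, m: int) -> np.ndarray:
    """All C(n_total, m) index subsets of size m, one row each."""
    return np.array(list(itertools.combinations(range(n_total), m)), dtype=np.intp)


def mann_whitney_exact(a, b, enumeration_cap: int = ENUMERATION_CAP,
                       ) -> tuple[float, float]:
    """Min-convention U statistic and two-sided exact p-value.

    The p-value is the fraction of all group labelings of the pooled sample
    whose min(U, mn-U) is at least as extreme (<=) as observed; ties enter
    through mid-ranks, so U may be half-integer. With identical groups the
    p-value is 1 by symmetry. Above ``enumeration_cap`` labelings a
    tie-corrected normal approximation with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[:m].sum()
    u_a = r_a - m * (m + 1) / 2.0
    u_b = m * n - u_a
    u_min = min(u_a, u_b)

    if comb(m + n, m) <= enumeration_cap:
        subsets = _labeling_matrix(m + n, m)
        rank_sums = ranks[subsets].sum(axis=1)
        u = rank_sums - m * (m + 1) / 2.0
        u_small = np.minimum(u, m * n - u)
        p = float(np.mean(u_small <= u_min + 1e-9))
    else:
        # tie-corrected normal approximation, continuity-corrected
        n_tot = m + n
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum()
        var = m * n / 12.0 * (n_tot + 1 - tie_term / (n_tot * (n_tot - 1)))
        if var == 0:  # all values identical
            return u_min, 1.0
        z = (u_min - m * n / 2.0 + 0.5) / sqrt(var)
        p = float(min(1.0, 2.0 * norm.cdf(z)))
    return u_min, p


# ---------------------------------------------------------------------------
# aggregation and comparisons

def class_total(norm: pd.DataFrame, cat: LipidCatalogue, lipid_class: str) -> pd.Series:
    """Per-sample sum of normalized values over all species of one class."""
    members = [sp.name for sp in cat.species_in_class(lipid_class) if sp.name in norm.index]
    if not members:
        raise KeyError(f"no species of class {lipid_class!r} in the table")
    total = norm.loc[members].sum(axis=0)
    total.name = lipid_class
    return total


def class_totals_table(norm: pd.DataFrame, cat: LipidCatalogue) -> pd.DataFrame:
    """Class x sample matrix of class totals, for every class present."""
    present = [c for c in cat.classes
               if any(sp.name in norm.index for sp in cat.species_in_class(c))]
    table = pd.DataFrame([class_total(norm, cat, c) for c in present])
    table.index.name = "class"
    return table


def compare_units(values: pd.DataFrame, sheet: pd.DataFrame, contrast: Contrast,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney comparison of every row of ``values`` across one contrast.

    Returns one row per unit (species or class) with group sizes and means,
    the min-convention U, the exact two-sided p, a Benjamini-Hochberg q
    (reported for reference only -- direction calls use the per-test alpha),
    and the direction call: increased / decreased when p < alpha and the
    test-cell mean is above / below the reference mean, otherwise unchanged.
    Equal means with p < alpha are flagged ``tied``.
    """
    test_samples = samples_in_cell(sheet, contrast.test)
    ref_samples = samples_in_cell(sheet, contrast.ref)
    if not test_samples or not ref_samples:
        empty = contrast.test if not test_samples else contrast.ref
        raise ValueError(f"contrast cell {empty} has no samples")

    records = []
    for unit in values.index:
        x = values.loc[unit, test_samples].to_numpy(dtype=float)
        y = values.loc[unit, ref_samples].to_numpy(dtype=float)
        u, p = mann_whitney_exact(x, y)
        records.append((unit, len(x), len(y), x.mean(), y.mean(), u, p))
    out = pd.DataFrame(records, columns=[
        "unit", "n_test", "n_ref", "mean_test", "mean_ref", "U", "p",
    ]).set_index("unit")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["contrast"] = contrast.name

    def call(row) -> str:
        if row["p"] >= alpha:
            return "unchanged"
        if row["mean_test"] > row["mean_ref"]:
            return "increased"
        if row["mean_test"] < row["mean_ref"]:
            return "decreased"
        return "tied"

    out["direction"] = out.apply(call, axis=1)
    return out


def venn_counts(results: pd.DataFrame, partition: dict[str, str]) -> pd.DataFrame:
    """Per-partition-cell (increased, decreased) counts of significant units.

    ``partition`` maps every unit to a category (e.g. species -> lipid
    category). Counts over all cells sum to the number of significant units.
    """
    unmapped = [u for u in results.index if u not in partition]
    if unmapped:
        raise KeyError(f"units missing from partition: {unmapped[:5]}")
    cells = sorted(set(partition[u] for u in results.index))
    counts = pd.DataFrame(0, index=pd.Index(cells, name="category"),
                          columns=["increased", "decreased"])
    for unit, row in results.iterrows():
        if row["direction"] in ("increased", "decreased"):
            counts.loc[partition[unit], row["direction"]] += 1
    return counts


def fold_change_matrix(class_totals: pd.DataFrame, sheet: pd.DataFrame,
                       contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS,
                       ) -> pd.DataFrame:
    """Class x contrast matrix of mean-ratio fold changes.

    Entry = mean(class total over test cell) / mean(over reference cell).
    """
    out = pd.DataFrame(index=class_totals.index,
                       columns=[c.name for c in contrasts], dtype=float)
    for contrast in contrasts:
        test = samples_in_cell(sheet, contrast.test)
        ref = samples_in_cell(sheet, contrast.ref)
        if not test or not ref:
            raise ValueError(f"contrast {contrast.name} has an empty cell")
        ref_mean = class_totals[ref].mean(axis=1)
        if (ref_mean == 0).any():
            bad = list(class_totals.index[ref_mean == 0])
            raise ZeroDivisionError(f"zero reference mean for class(es) {bad}")
        out[contrast.name] = class_totals[test].mean(axis=1) / ref_mean
    out.index.name = "class"
    return out
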