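"""Targeted arachidonate-metabolite (eicosanoid) analysis.

The panel follows the three enzymatic branches downstream of free
arachidonate (20:4): cyclooxygenase (COX) products PGD2, TXB2 and 12-HHT;
the lipoxygenase (LOX) product 5-HETE; and the cytochrome-P450 (CYP)
product 18-HETE. Peak areas are first normalized to the spiked deuterated
leukotriene standard, then optionally expressed relative to arachidonate in
the same sample -- the latter view separates relative pathway activity from
precursor depletion, and is invariant to the standard normalization (the
standard cancels in the ratio).
"""

from __future__ import annotations

import pandas as pd

from .normalize import EICOSANOID_STANDARD, NormalizationError
from .profile_stats import Cell, samples_in_cell

#: metabolite -> pathway; a total partition of the default panel
PATHWAYS: dict[str, str] = {
    "arachidonate": "precursor",
    "PGD2": "COX",
    "TXB2": "COX",
    "12-HHT": "COX",
    "5-HETE": "LOX",
    "18-HETE": "CYP",
}

DEFAULT_PANEL = tuple(PATHWAYS)


def normalize_areas(raw: pd.DataFrame, standard: str = EICOSANOID_STANDARD,
                    ) -> pd.DataFrame:
    """Per-sample ratio of metabolite peak areas to the internal standard.

    The standard row is removed from the output.
    """
    if standard not in raw.index:
        raise NormalizationError(f"standard channel {standard!r} missing from table")
    std = raw.loc[standard]
    bad = list(raw.columns[std <= 0])
    if bad:
        raise NormalizationError(f"standard {standard!r} is not positive in sample(s) {bad}")
    return raw.drop(index=standard) / std


def relative_to_arachidonate(table: pd.DataFrame,
                             precursor: str = "arachidonate") -> pd.DataFrame:
    """Express every metabolite as a per-sample ratio to the precursor.

    The precursor row becomes identically 1. Works on raw or
    standard-normalized areas alike (the standard cancels).
    """
    if precursor not in table.index:
        raise KeyError(f"precursor {precursor!r} missing from table")
    ref = table.loc[precursor]
    bad = list(table.columns[ref <= 0])
    if bad:
        raise ZeroDivisionError(f"{precursor} is not positive in sample(s) {bad}")
    return table / ref


def pathway_means(ratios: pd.DataFrame, pathways: dict[str, str] | None = None,
                  ) -> pd.DataFrame:
    """Per-sample mean ratio of each pathway's member metabolites.

    This is the unit on which pathway-level group tests run: averaging the
    members damps metabolite-specific noise while the shared precursor
    denominator is untouched.
    """
    pathways = pathways or PATHWAYS
    unmapped = [m for m in ratios.index if m not in pathways]
    if unmapped:
        raise KeyError(f"metabolites without a pathway: {unmapped}")
    out = ratios.groupby([pathways[m] for m in ratios.index]).mean()
    out.index.name = "pathway"
    return out


def pathway_summary(ratios: pd.DataFrame, sheet: pd.DataFrame,
                    pathways: dict[str, str] | None = None) -> pd.DataFrame:
    """Mean ratio per pathway per (group, age) cell.

    Every metabolite row must map to exactly one pathway.
    """
    pathways = pathways or PATHWAYS
    unmapped = [m for m in ratios.index if m not in pathways]
    if unmapped:
        raise KeyError(f"metabolites without a pathway: {unmapped}")
    cells: list[Cell] = sorted(
        {(g, a) for g, a in zip(sheet["group"], sheet["age_weeks"])})
    path_index = sorted(set(pathways[m] for m in ratios.index))
    out = pd.DataFrame(index=pd.Index(path_index, name="pathway"),
                       columns=[f"{g}-{a}w" for g, a in cells], dtype=float)
    for cell, col in zip(cells, out.columns):
        samples = samples_in_cell(sheet, cell)
        cell_means = ratios[samples].mean(axis=1)
        grouping = cell_means.groupby([pathways[m] for m in ratios.index])
        out[col] = grouping.mean()
    return out
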