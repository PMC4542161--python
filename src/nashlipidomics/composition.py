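"""Within-class composition and fatty-acyl side-chain analysis.

Two complementary views of how a lipid class is remodelled between groups
while its total abundance stays flat:

* per-species share of the class total (percent), and the signed
  percentage-point change between groups, with a >1 point filter for the
  biologically notable movers;
* per-fatty-acyl side-chain fractions: the share of one acyl (e.g. 16:0,
  palmitate) among all acyl chains of a diacyl phospholipid class, computed
  as sum(peak heights weighted by matching-chain multiplicity) divided by
  2 x sum(all class peak heights) -- each PC or PE carries two chains.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalogue import LipidCatalogue, LipidSpecies, Linkage
from .profile_stats import Cell, samples_in_cell

#: classes with exactly two acyl chains per molecule (diacyl glycerophospholipids)
TWO_CHAIN_CLASSES = frozenset({"PC", "PE", "PG", "PI", "BMP"})


def _class_values(norm: pd.DataFrame, cat: LipidCatalogue, lipid_class: str) -> pd.DataFrame:
    members = [sp.name for sp in cat.species_in_class(lipid_class) if sp.name in norm.index]
    if not members:
        raise KeyError(f"no species of class {lipid_class!r} in the table")
    return norm.loc[members]


def species_percent_within_class(norm: pd.DataFrame, cat: LipidCatalogue,
                                 sheet: pd.DataFrame, lipid_class: str,
                                 cell: Cell) -> pd.Series:
    """Mean per-species percent of the class total over one (group, age) cell.

    Percentages are computed per sample (100 x value / class total in that
    sample) and then averaged over the cell's samples, so they sum to 100
    per group and are invariant to per-sample rescaling.
    """
    samples = samples_in_cell(sheet, cell)
    if not samples:
        raise ValueError(f"no samples in cell {cell}")
    values = _class_values(norm, cat, lipid_class)[samples]
    totals = values.sum(axis=0)
    zero = [s for s in samples if totals[s] == 0]
    if zero:
        raise ZeroDivisionError(f"class {lipid_class} total is zero in sample(s) {zero}")
    return (100.0 * values / totals).mean(axis=1)


def percent_change(pct_ref: float, pct_contrast: float) -> float:
    """Signed percentage-point difference, contrast minus reference."""
    return pct_contrast - pct_ref


def composition_profile(norm: pd.DataFrame, cat: LipidCatalogue, sheet: pd.DataFrame,
                        lipid_class: str, ref_cell: Cell, test_cell: Cell,
                        threshold: float = 1.0) -> pd.DataFrame:
    """Per-species composition panel for one class and one group contrast.

    Columns: chain string, mean percent in each cell, signed percentage-point
    change (test minus reference) and whether |change| exceeds ``threshold``.
    """
    from .catalogue import format_chain_assignment
    pct_ref = species_percent_within_class(norm, cat, sheet, lipid_class, ref_cell)
    pct_test = species_percent_within_class(norm, cat, sheet, lipid_class, test_cell)
    chains = {sp.name: format_chain_assignment(sp.chain_assignments)
              for sp in cat.species_in_class(lipid_class)}
    out = pd.DataFrame({
        "chains": [chains[n] for n in pct_ref.index],
        "pct_ref": pct_ref,
        "pct_test": pct_test,
    })
    out["pct_change"] = out["pct_test"] - out["pct_ref"]
    out["large_change"] = out["pct_change"].abs() > threshold
    out.index.name = "species"
    return out


def reference_panel() -> pd.DataFrame:
    """The packaged measured PC/PE composition panel.

    One row per PC or PE species with its chain assignment, the mean percent
    of the class total in each 8-week group, and the published
    percentage-point change (STAM minus HFD control) as printed, to two
    decimals. Indexed by species name.
    """
    from . import io as _io
    path = resources.files("nashlipidomics") / "data" / "pc_pe_panel.tsv"
    with resources.as_file(path) as p:
        rows, header = _io.read_tsv_rows(p)
    df = pd.DataFrame(rows, columns=header).set_index("species")
    for col in ("pct_hfd", "pct_stam", "printed_change"):
        df[col] = df[col].astype(float)
    return df


def flag_large_changes(pct_change: pd.Series, threshold: float = 1.0) -> list[str]:
    """Species whose |percentage-point change| exceeds ``threshold``, largest first."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = pct_change[pct_change.abs() > threshold]
    return list(hits.abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# fatty-acyl side-chain fractions

def acyl_multiplicity(sp: LipidSpecies, fa_key: str,
                      weighting: str = "multiplicity") -> float:
    """Expected number of chains of ``sp`` matching the carbons:double-bonds key.

    Ether and plasmalogen chains match by their printed label (16:0p and
    16:0e both match "16:0"); sphingoid bases never match. With several
    alternative chain sets, the species distributes equally across them, so
    the multiplicity is the mean of the per-set counts. ``weighting="presence"``
    caps each set's count at 1 (a homo-diacyl species counted once).
    """
    if weighting not in ("multiplicity", "presence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not sp.chain_assignments:
        return 0.0
    counts = []
    for chains in sp.chain_assignments:
        k = sum(1 for a in chains
                if a.linkage is not Linkage.SPHINGOID and a.key == fa_key)
        counts.append(min(k, 1) if weighting == "presence" else k)
    return sum(counts) / len(counts)


def _undetermined_multiplicity(sp: LipidSpecies, n_chains: int = 2) -> float:
    """Chains of ``sp`` not accounted for by any determined assignment."""
    if not sp.chain_assignments:
        return float(n_chains)
    per_set = [n_chains - sum(1 for a in chains if a.linkage is not Linkage.SPHINGOID)
               for chains in sp.chain_assignments]
    return max(0.0, sum(per_set) / len(per_set))


def sidechain_fraction(norm: pd.DataFrame, cat: LipidCatalogue, sheet: pd.DataFrame,
                       lipid_class: str, fa_key: str, cell: Cell,
                       weighting: str = "multiplicity") -> float:
    """Share of one fatty acyl among all side chains of a two-chain class.

    Per sample: sum over species of (value x matching-chain multiplicity)
    divided by 2 x sum of all class species values; the returned value is the
    mean over the cell's samples. Species with undetermined chains count in
    the denominator only.
    """
    table = sidechain_fraction_table(norm, cat, sheet, lipid_class, (cell,),
                                     fa_keys=(fa_key,), weighting=weighting)
    return float(table.loc[fa_key].iloc[0])


def sidechain_fraction_table(norm: pd.DataFrame, cat: LipidCatalogue,
                             sheet: pd.DataFrame, lipid_class: str,
                             cells: tuple[Cell, ...],
                             fa_keys: tuple[str, ...] | None = None,
                             weighting: str = "multiplicity") -> pd.DataFrame:
    """Side-chain fraction matrix: fatty acyl (plus "undetermined") x cell.

    When every species has one fully determined chain set, the fraction
    column sums to 1; undetermined chains are reported in their own row so
    the column total is always 1 under multiplicity weighting.
    """
    if lipid_class not in TWO_CHAIN_CLASSES:
        raise ValueError(f"{lipid_class!r} is not a two-chain phospholipid class")
    species = [sp for sp in cat.species_in_class(lipid_class) if sp.name in norm.index]
    if not species:
        raise KeyError(f"no species of class {lipid_class!r} in the table")

    if fa_keys is None:
        seen: dict[str, None] = {}
        for sp in species:
            for chains in sp.chain_assignments:
                for a in chains:
                    if a.linkage is not Linkage.SPHINGOID:
                        seen.setdefault(a.key, None)
        fa_keys = tuple(sorted(seen, key=lambda k: tuple(map(int, k.split(":")))))

    names = [sp.name for sp in species]
    out = pd.DataFrame(index=pd.Index([*fa_keys, "undetermined"], name="fatty_acyl"),
                       columns=[f"{g}-{a}w" for g, a in cells], dtype=float)
    for cell, col in zip(cells, out.columns):
        samples = samples_in_cell(sheet, cell)
        if not samples:
            raise ValueError(f"no samples in cell {cell}")
        values = norm.loc[names, samples]
        denom = 2.0 * values.sum(axis=0)
        zero = [s for s in samples if denom[s] == 0]
        if zero:
            raise ZeroDivisionError(
                f"class {lipid_class} total is zero in sample(s) {zero}")
        for key in fa_keys:
            mult = pd.Series({sp.name: acyl_multiplicity(sp, key, weighting)
                              for sp in species})
            numer = values.mul(mult, axis=0).sum(axis=0)
            out.loc[key, col] = float((numer / denom).mean())
        undet = pd.Series({sp.name: _undetermined_multiplicity(sp) for sp in species})
        out.loc["undetermined", col] = float(
            (values.mul(undet, axis=0).sum(axis=0) / denom).mean())
    return out
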