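"""Seeded generator of synthetic two-group x two-age lipidomics studies.

The generator emulates the statistical skeleton the analysis assumes: a
2 (HFD control vs STAM) x 2 (8 vs 12 weeks) design with five livers per
cell, ~250 catalogued species with log-normal intensities (independent
across species), multiplicative group effects on classes or on fatty-acyl
side chains, and internal-standard channels with their own per-sample
noise. Every programmed effect is recorded in a truth table so recovery can
be scored without peeking at the pipeline.

Fatty-acyl effects scale each species by ``effect ** (k/2)`` where k is the
species' matching-chain multiplicity (0..2): a homo-diacyl species takes the
full effect, a single-chain match takes its square root. Applying a paired
down/up effect to two acyls therefore shifts the class's side-chain
composition while roughly preserving its total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .catalogue import CLASS_INFO, LipidCatalogue
from .composition import acyl_multiplicity
from .eicosanoids import PATHWAYS
from .normalize import EICOSANOID_STANDARD, StandardMap
from .profile_stats import Cell


@dataclass(frozen=True)
class EffectSpec:
    """One programmed multiplicative group effect; 1.0 is the null."""

    kind: str          # "class" | "acyl" | "metabolite" | "pathway"
    target: str        # class name, fatty-acyl key, metabolite, or pathway
    cell: Cell         # (group, age_weeks) the effect applies to
    effect: float
    lipid_class: str | None = None   # required for acyl effects
    ref_cell: Cell | None = None     # the contrast cell recovery is scored against

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect size must be > 0")
        if self.kind == "acyl" and self.lipid_class is None:
            raise ValueError("acyl effects need a lipid_class")

    @property
    def expected_direction(self) -> str:
        if self.effect > 1:
            return "increased"
        if self.effect < 1:
            return "decreased"
        return "unchanged"


@dataclass(frozen=True)
class StudyDesign:
    """Design constants of the emulated study."""

    groups: tuple[str, ...] = ("HFD", "STAM")
    ages: tuple[int, ...] = (8, 12)
    n_per_cell: int = 5
    #: per-species baseline medians are drawn log-uniformly over this log10 range
    baseline_log10_range: tuple[float, float] = (3.0, 5.0)
    species_cv: float = 0.20
    standard_cv: float = 0.10
    standard_nominal: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("need n >= 2 per cell")
        if self.species_cv <= 0 or self.standard_cv <= 0:
            raise ValueError("coefficients of variation must be > 0")

    @property
    def cells(self) -> list[Cell]:
        return [(g, a) for g in self.groups for a in self.ages]

    def sample_ids(self) -> list[str]:
        return [f"{g}{a}w_{i + 1}"
                for g, a in self.cells for i in range(self.n_per_cell)]

    def sample_sheet(self) -> pd.DataFrame:
        recs = [(f"{g}{a}w_{i + 1}", g, a)
                for g, a in self.cells for i in range(self.n_per_cell)]
        return pd.DataFrame(recs, columns=["sample", "group", "age_weeks"]
                            ).set_index("sample")


#: reported study presets; effects mirror the directions seen in the liver data
PRESETS: dict[str, list[EffectSpec]] = {
    "null": [],
    # NASH vs steatosis at 8 weeks: sphingolipids and CoQ up, DG/TG down
    "nash8w": [
        EffectSpec("class", "SM", ("STAM", 8), 2.5, ref_cell=("HFD", 8)),
        EffectSpec("class", "Cer", ("STAM", 8), 2.5, ref_cell=("HFD", 8)),
        EffectSpec("class", "CoQ", ("STAM", 8), 2.5, ref_cell=("HFD", 8)),
        EffectSpec("class", "DG", ("STAM", 8), 0.4, ref_cell=("HFD", 8)),
        EffectSpec("class", "TG", ("STAM", 8), 0.4, ref_cell=("HFD", 8)),
    ],
    # NASH -> fibrosis progression: acylcarnitines accumulate by 12 weeks
    "fibrosis12w": [
        EffectSpec("class", "Car", ("STAM", 12), 2.5, ref_cell=("STAM", 8)),
    ],
    # palmitate -> stearate substitution in PC/PE side chains, totals preserved
    "sidechain8w": [
        EffectSpec("acyl", "16:0", ("STAM", 8), 0.5, lipid_class="PC", ref_cell=("HFD", 8)),
        EffectSpec("acyl", "18:0", ("STAM", 8), 2.0, lipid_class="PC", ref_cell=("HFD", 8)),
        EffectSpec("acyl", "16:0", ("STAM", 8), 0.5, lipid_class="PE", ref_cell=("HFD", 8)),
        EffectSpec("acyl", "18:0", ("STAM", 8), 2.0, lipid_class="PE", ref_cell=("HFD", 8)),
    ],
}

#: eicosanoid presets: precursor and LOX/CYP products depleted, COX spared,
#: so arachidonate-relative COX ratios roughly double
EICOSANOID_PRESETS: dict[str, list[EffectSpec]] = {
    "null": [],
    "cox8w": [
        EffectSpec("metabolite", "arachidonate", ("STAM", 8), 0.5, ref_cell=("HFD", 8)),
        EffectSpec("metabolite", "5-HETE", ("STAM", 8), 0.5, ref_cell=("HFD", 8)),
        EffectSpec("metabolite", "18-HETE", ("STAM", 8), 0.5, ref_cell=("HFD", 8)),
    ],
}

#: nominal peak areas for the targeted panel (precursor >> products)
_EICOSANOID_BASELINES = {
    "arachidonate": 50.0,
    "PGD2": 0.5,
    "TXB2": 0.4,
    "12-HHT": 0.6,
    "5-HETE": 1.0,
    "18-HETE": 0.3,
}


def _sigma(cv: float) -> float:
    return sqrt(log(1.0 + cv * cv))


def _truth_table(effects: list[EffectSpec]) -> pd.DataFrame:
    recs = [{
        "kind": e.kind, "target": e.target,
        "lipid_class": e.lipid_class or "",
        "group": e.cell[0], "age_weeks": e.cell[1],
        "ref_group": (e.ref_cell or ("", ""))[0],
        "ref_age_weeks": (e.ref_cell or ("", ""))[1],
        "effect": e.effect, "expected_direction": e.expected_direction,
    } for e in effects]
    return pd.DataFrame(recs, columns=[
        "kind", "target", "lipid_class", "group", "age_weeks",
        "ref_group", "ref_age_weeks", "effect", "expected_direction"])


def generate_study(design: StudyDesign, effects: list[EffectSpec],
                   cat: LipidCatalogue, seed: int,
                   standard_map: StandardMap | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic study: (raw peak table, sample sheet, truth table).

    The peak table carries every catalogued species plus one row per
    internal-standard channel. Identical seeds give identical tables.
    """
    standard_map = standard_map or StandardMap.default()
    for e in effects:
        if e.kind == "class":
            if e.target not in CLASS_INFO or not cat.species_in_class(e.target):
                raise KeyError(f"effect target class {e.target!r} not in catalogue")
        elif e.kind == "acyl":
            if not cat.species_in_class(e.lipid_class):
                raise KeyError(f"acyl effect class {e.lipid_class!r} not in catalogue")
        else:
            raise KeyError(f"effect kind {e.kind!r} not applicable to a lipid study")

    rng = np.random.default_rng(seed)
    sheet = design.sample_sheet()
    samples = list(sheet.index)
    names = cat.names
    lo, hi = design.baseline_log10_range
    baselines = 10.0 ** rng.uniform(lo, hi, size=len(names))
    noise = rng.lognormal(0.0, _sigma(design.species_cv),
                          size=(len(names), len(samples)))
    values = baselines[:, None] * noise

    multiplier = pd.DataFrame(1.0, index=names, columns=samples)
    for e in effects:
        cols = [s for s in samples
                if sheet.loc[s, "group"] == e.cell[0]
                and sheet.loc[s, "age_weeks"] == e.cell[1]]
        if e.kind == "class":
            rows = [sp.name for sp in cat.species_in_class(e.target)]
            multiplier.loc[rows, cols] *= e.effect
        else:  # acyl
            for sp in cat.species_in_class(e.lipid_class):
                k = acyl_multiplicity(sp, e.target)
                if k > 0:
                    multiplier.loc[sp.name, cols] *= e.effect ** (k / 2.0)

    peak = pd.DataFrame(values, index=pd.Index(names, name="name"),
                        columns=samples) * multiplier
    for channel in standard_map.standard_channels:
        peak.loc[channel] = design.standard_nominal * rng.lognormal(
            0.0, _sigma(design.standard_cv), size=len(samples))
    return peak, sheet, _truth_table(effects)


def generate_eicosanoid_study(design: StudyDesign, effects: list[EffectSpec],
                              seed: int,
                              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic targeted panel: (raw area table incl. standard row, sheet, truth)."""
    for e in effects:
        if e.kind == "metabolite":
            if e.target not in _EICOSANOID_BASELINES:
                raise KeyError(f"unknown metabolite {e.target!r}")
        elif e.kind == "pathway":
            if e.target not in set(PATHWAYS.values()):
                raise KeyError(f"unknown pathway {e.target!r}")
        else:
            raise KeyError(f"effect kind {e.kind!r} not applicable to eicosanoids")

    rng = np.random.default_rng(seed)
    sheet = design.sample_sheet()
    samples = list(sheet.index)
    metabolites = list(_EICOSANOID_BASELINES)
    base = np.array([_EICOSANOID_BASELINES[m] for m in metabolites])
    noise = rng.lognormal(0.0, _sigma(design.species_cv),
                          size=(len(metabolites), len(samples)))
    area = pd.DataFrame(base[:, None] * noise,
                        index=pd.Index(metabolites, name="name"), columns=samples)
    for e in effects:
        cols = [s for s in samples
                if sheet.loc[s, "group"] == e.cell[0]
                and sheet.loc[s, "age_weeks"] == e.cell[1]]
        if e.kind == "metabolite":
            area.loc[e.target, cols] *= e.effect
        else:
            members = [m for m, p in PATHWAYS.items() if p == e.target]
            area.loc[members, cols] *= e.effect
    area.loc[EICOSANOID_STANDARD] = rng.lognormal(
        0.0, _sigma(design.standard_cv), size=len(samples))
    return area, sheet, _truth_table(effects)


def write_study(out_dir: str | Path, peak: pd.DataFrame, sheet: pd.DataFrame,
                truth: pd.DataFrame, eico: pd.DataFrame | None = None) -> list[Path]:
    """Write a generated study as the TSV dialects the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    _io.write_matrix(out / "peak_table.tsv", peak)
    written.append(out / "peak_table.tsv")
    _io.write_sample_sheet(out / "samples.tsv", sheet)
    written.append(out / "samples.tsv")
    _io.write_tsv_rows(out / "truth.tsv", truth.columns,
                       truth.to_numpy().tolist())
    written.append(out / "truth.tsv")
    if eico is not None:
        _io.write_matrix(out / "eicosanoid_areas.tsv", eico)
        written.append(out / "eicosanoid_areas.tsv")
    return written
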