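"""Internal-standard normalization of raw peak tables.

Each spiked-in standard indexes per-sample extraction recovery and detector
response for one chemical category/ion-mode stratum, so normalization is a
plain per-sample ratio: species intensity divided by the intensity of the
matched standard channel in the same sample. No cross-sample scaling is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalogue import LipidCatalogue, LipidSpecies


class NormalizationError(ValueError):
    """Missing or unusable internal-standard channel."""


@dataclass(frozen=True)
class StandardRule:
    """Route species to a standard channel by class (takes precedence) or category."""

    standard: str
    category: str | None = None
    lipid_class: str | None = None
    ion_mode: str | None = None

    def matches(self, sp: LipidSpecies) -> bool:
        if self.lipid_class is not None:
            return sp.lipid_class == self.lipid_class
        if self.category is not None and sp.category != self.category:
            return False
        if self.ion_mode is not None and sp.ion_mode != self.ion_mode:
            return False
        return self.category is not None


@dataclass
class StandardMap:
    """Ordered rules mapping every catalogued species to one standard channel.

    Class-level rules are checked before category-level rules, so cardiolipin
    (a positive-mode phospholipid) can share the triacylglycerol standard used
    for neutral lipids while the other phospholipids use the deuterated PC.
    """

    class_rules: list[StandardRule] = field(default_factory=list)
    category_rules: list[StandardRule] = field(default_factory=list)

    @classmethod
    def default(cls) -> "StandardMap":
        return cls(
            class_rules=[
                StandardRule(standard="8:0/8:0/18:2 TG", lipid_class="CL"),
            ],
            category_rules=[
                StandardRule(standard="16:0/16:0 PC-d6", category="phospholipid",
                             ion_mode="negative"),
                StandardRule(standard="16:0/16:0 PC-d6", category="sphingolipid",
                             ion_mode="negative"),
                StandardRule(standard="8:0/8:0/18:2 TG", category="neutral lipid",
                             ion_mode="positive"),
                StandardRule(standard="16:0 LPC-d3", category="free fatty acid",
                             ion_mode="negative"),
                StandardRule(standard="12:0/12:0 PE", category="acylcarnitine",
                             ion_mode="positive"),
            ],
        )

    @property
    def standard_channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for rule in [*self.class_rules, *self.category_rules]:
            seen.setdefault(rule.standard, None)
        return list(seen)


#: standard channel for the targeted eicosanoid panel (peak areas)
EICOSANOID_STANDARD = "Leukotriene B4-d4"


def match_standard(species: LipidSpecies, standard_map: StandardMap | None = None) -> str:
    """Name of the internal-standard channel that normalizes ``species``."""
    standard_map = standard_map or StandardMap.default()
    for rule in standard_map.class_rules:
        if rule.matches(species):
            return rule.standard
    for rule in standard_map.category_rules:
        if rule.matches(species):
            return rule.standard
    raise NormalizationError(
        f"no standard rule matches {species.name} "
        f"({species.category}, {species.ion_mode})")


def split_standard_rows(raw: pd.DataFrame, standard_map: StandardMap | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate a raw table into (species rows, standard-channel rows)."""
    standard_map = standard_map or StandardMap.default()
    channels = [c for c in standard_map.standard_channels if c in raw.index]
    species = raw.drop(index=channels)
    return species, raw.loc[channels]


def normalize_table(raw: pd.DataFrame, cat: LipidCatalogue,
                    standard_map: StandardMap | None = None) -> pd.DataFrame:
    """Divide every species row by its matched standard channel, per sample.

    ``raw`` is species (and standard channels) x samples. Standard rows are
    removed from the output. A missing standard channel, or a standard that
    is not strictly positive in some sample, is a hard error.
    """
    standard_map = standard_map or StandardMap.default()
    species_df, _ = split_standard_rows(raw, standard_map)

    unknown = [n for n in species_df.index if n not in cat]
    if unknown:
        raise KeyError(f"species not in catalogue: {unknown[:5]}"
                       + ("..." if len(unknown) > 5 else ""))

    needed = {match_standard(cat.get(n), standard_map) for n in species_df.index}
    missing = sorted(needed - set(raw.index))
    if missing:
        raise NormalizationError(f"standard channel(s) missing from table: {missing}")
    for channel in sorted(needed):
        bad = raw.columns[raw.loc[channel] <= 0]
        if len(bad):
            raise NormalizationError(
                f"standard {channel!r} is not positive in sample(s) {list(bad)}")

    out = species_df.copy()
    for name in out.index:
        out.loc[name] = species_df.loc[name] / raw.loc[match_standard(cat.get(name), standard_map)]
    return out
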