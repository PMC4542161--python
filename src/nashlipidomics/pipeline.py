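"""End-to-end orchestration: config, cross-validation, report bundle.

``run_pipeline`` reads the raw peak table, sample sheet and catalogue,
cross-validates them, and writes a deterministic bundle of TSV artifacts:
the normalized table, class totals, per-contrast comparison tables, Venn
counts of significant species per lipid category, the class fold-change
matrix (linear and log2), composition panels and side-chain fractions for
the diacyl phospholipid classes, eicosanoid tables when a targeted panel is
provided, and a JSON manifest (config hash, package and library versions).
All artifacts are computed in memory first; nothing is written on error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as _io
from .catalogue import LipidCatalogue, reference_catalogue, validate_catalogue
from .composition import TWO_CHAIN_CLASSES, composition_profile, sidechain_fraction_table
from .eicosanoids import normalize_areas, pathway_summary, relative_to_arachidonate
from .normalize import StandardMap, normalize_table, split_standard_rows
from .profile_stats import (DEFAULT_CONTRASTS, Contrast, class_totals_table,
                            compare_units, fold_change_matrix, venn_counts)

log = logging.getLogger("nashlipidomics")

_CONTRAST_RE = re.compile(r"^(\w+)-(\d+)w_vs_(\w+)-(\d+)w$")


class ConfigError(ValueError):
    """Invalid run configuration."""


def parse_contrast(text: str) -> Contrast:
    m = _CONTRAST_RE.match(text)
    if m is None:
        raise ConfigError(
            f"bad contrast {text!r}; expected e.g. 'STAM-8w_vs_HFD-8w'")
    return Contrast(test=(m.group(1), int(m.group(2))),
                    ref=(m.group(3), int(m.group(4))))


@dataclass
class RunConfig:
    peak_table: str
    sample_sheet: str
    out_dir: str
    catalogue: str | None = None          # default: packaged reference
    eicosanoid_table: str | None = None
    alpha: float = 0.05
    threshold: float = 1.0                # composition filter, percentage points
    contrasts: list[str] = field(
        default_factory=lambda: [c.name for c in DEFAULT_CONTRASTS])
    composition_classes: list[str] = field(default_factory=lambda: ["PC", "PE"])
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.threshold < 0:
            raise ConfigError("composition threshold must be >= 0")
        for c in self.contrasts:
            parse_contrast(c)
        for cls in self.composition_classes:
            if cls not in TWO_CHAIN_CLASSES:
                raise ConfigError(
                    f"composition class {cls!r} is not a two-chain phospholipid class")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"peak_table", "sample_sheet", "out_dir"} - set(data)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    def digest(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, LipidCatalogue,
                                             pd.DataFrame | None]:
    for path in [config.peak_table, config.sample_sheet, config.catalogue,
                 config.eicosanoid_table]:
        if path is not None and not Path(path).exists():
            raise ConfigError(f"input file not found: {path}")
    cat = (LipidCatalogue.from_tsv(config.catalogue) if config.catalogue
           else reference_catalogue())
    peak = _io.read_matrix(config.peak_table)
    sheet = _io.read_sample_sheet(config.sample_sheet)
    eico = (_io.read_matrix(config.eicosanoid_table)
            if config.eicosanoid_table else None)
    return peak, sheet, cat, eico


def cross_validate(peak: pd.DataFrame, sheet: pd.DataFrame, cat: LipidCatalogue,
                   standard_map: StandardMap | None = None) -> None:
    """Check table/sheet/catalogue agreement before any computation."""
    species, _ = split_standard_rows(peak, standard_map)
    unknown = [n for n in species.index if n not in cat]
    if unknown:
        raise ConfigError(f"peak-table species not in catalogue: {unknown[:10]}")
    no_sheet = [c for c in peak.columns if c not in sheet.index]
    if no_sheet:
        raise ConfigError(f"peak-table samples missing from sample sheet: {no_sheet}")
    report = validate_catalogue(cat)
    if not report.ok:
        msgs = [f"{i.species}: {i.check}: {i.message}" for i in report.issues[:10]]
        raise ConfigError("catalogue validation failed:\n" + "\n".join(msgs))
    for cell in {(g, a) for g, a in zip(sheet["group"], sheet["age_weeks"])}:
        n = int(((sheet["group"] == cell[0]) & (sheet["age_weeks"] == cell[1])).sum())
        if n < 2:
            raise ConfigError(f"design cell {cell} has n={n} < 2")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns artifact paths."""
    logging.basicConfig(level=config.log_level)
    peak, sheet, cat, eico = _load_inputs(config)
    standard_map = StandardMap.default()
    cross_validate(peak, sheet, cat, standard_map)
    contrasts = [parse_contrast(c) for c in config.contrasts]
    for contrast in contrasts:
        for cell in (contrast.test, contrast.ref):
            if not ((sheet["group"] == cell[0]) & (sheet["age_weeks"] == cell[1])).any():
                raise ConfigError(f"contrast cell {cell} has no samples")

    # ---- compute everything before writing anything -----------------------
    artifacts: dict[str, Callable[[Path], None]] = {}

    norm = normalize_table(peak, cat, standard_map)
    log.info("normalized %d species x %d samples", *norm.shape)
    artifacts["normalized.tsv"] = lambda p, df=norm: _io.write_matrix(p, df)

    totals = class_totals_table(norm, cat)
    artifacts["class_totals.tsv"] = lambda p, df=totals: _io.write_matrix(
        p, df, index_name="class")

    partition = {sp.name: sp.category for sp in cat}
    for contrast in contrasts:
        species_cmp = compare_units(norm, sheet, contrast, alpha=config.alpha)
        class_cmp = compare_units(totals, sheet, contrast, alpha=config.alpha)
        venn = venn_counts(species_cmp, partition)
        log.info("%s: %d/%d species significant at alpha=%g", contrast.name,
                 int((species_cmp["p"] < config.alpha).sum()), len(species_cmp),
                 config.alpha)
        for stem, df in [(f"comparison_species_{contrast.name}", species_cmp),
                         (f"comparison_class_{contrast.name}", class_cmp)]:
            artifacts[f"{stem}.tsv"] = lambda p, d=df: _io.write_tsv_rows(
                p, ["unit", *d.columns],
                [[i, *r] for i, r in zip(d.index, d.to_numpy())])
        artifacts[f"venn_counts_{contrast.name}.tsv"] = (
            lambda p, d=venn: _io.write_tsv_rows(
                p, ["category", *d.columns],
                [[i, *r] for i, r in zip(d.index, d.to_numpy())]))

    fc = fold_change_matrix(totals, sheet, tuple(contrasts))
    artifacts["fold_change.tsv"] = lambda p, df=fc: _io.write_matrix(
        p, df, index_name="class")
    artifacts["fold_change_log2.tsv"] = lambda p, df=np.log2(fc): _io.write_matrix(
        p, df, index_name="class")

    primary = contrasts[0]
    for cls in config.composition_classes:
        panel = composition_profile(norm, cat, sheet, cls, primary.ref,
                                    primary.test, threshold=config.threshold)
        artifacts[f"composition_{cls}.tsv"] = lambda p, d=panel: _io.write_tsv_rows(
            p, ["species", *d.columns],
            [[i, *r] for i, r in zip(d.index, d.to_numpy())])
    cells = tuple(dict.fromkeys([primary.ref, primary.test]))
    frac_frames = []
    for cls in config.composition_classes:
        t = sidechain_fraction_table(norm, cat, sheet, cls, cells)
        t.insert(0, "class", cls)
        frac_frames.append(t.reset_index())
    fracs = pd.concat(frac_frames, ignore_index=True)
    artifacts["sidechain_fractions.tsv"] = lambda p, d=fracs: _io.write_tsv_rows(
        p, list(d.columns), d.to_numpy().tolist())

    if eico is not None:
        eico_norm = normalize_areas(eico)
        ratios = relative_to_arachidonate(eico_norm)
        summary = pathway_summary(ratios, sheet)
        artifacts["eicosanoid_normalized.tsv"] = (
            lambda p, d=eico_norm: _io.write_matrix(p, d))
        artifacts["eicosanoid_ratios.tsv"] = (
            lambda p, d=ratios: _io.write_matrix(p, d))
        artifacts["eicosanoid_pathways.tsv"] = (
            lambda p, d=summary: _io.write_matrix(p, d, index_name="pathway"))

    manifest = {
        "config": asdict(config),
        "config_sha256": config.digest(),
        "package_version": __version__,
        "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "artifacts": sorted(artifacts),
    }

    # ---- write the bundle --------------------------------------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, writer in artifacts.items():
        writer(out / name)
        paths[name] = out / name
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest.json"] = out / "manifest.json"
    log.info("wrote %d artifacts to %s", len(paths), out)
    return paths
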