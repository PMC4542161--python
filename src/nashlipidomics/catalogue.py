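"""Lipid shorthand nomenclature and the species catalogue.

Species are named in the compact ``<carbons>:<double bonds><class>`` dialect
used by shotgun/LC-MS liver lipidomics, e.g. ``34:1PC`` (a phosphatidylcholine
with 34 acyl carbons and one double bond), ``38:5e/pPC`` (an ether or
plasmalogen PC), ``36:4PE-a`` (the first of two chromatographically resolved
isomers of the 36:4 PE formula).  Chain assignments, where the instrument
resolved them, are strings like ``16:0/18:1`` or ``d18:1/16:0`` (sphingoid
base), with alternatives separated by spaces (``14:0/18:2 16:1/16:1``) and
``n.d.`` when no assignment was made.

Double-bond accounting convention: an ether ("e") linkage contributes no
double bond to the shorthand total, while a plasmalogen ("p", vinyl-ether)
linkage contributes one.  Thus ``36:5e/pPE = 16:0p/20:4`` is consistent
(16 + 20 = 36 carbons; 0 + 4 + 1 = 5 double bonds).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class ParseError(ValueError):
    """Raised when a species name or chain string cannot be parsed."""


class Linkage(str, Enum):
    ESTER = "ester"
    ETHER = "ether"          # "e" suffix
    PLASMALOGEN = "plasmalogen"  # "p" suffix (vinyl ether)
    SPHINGOID = "sphingoid"  # "d" prefix (long-chain base)


#: lipid class -> (category, ion mode) for every class the pipeline knows.
CLASS_INFO: Mapping[str, tuple[str, str]] = {
    "LPC": ("phospholipid", "negative"),
    "PC": ("phospholipid", "negative"),
    "PE": ("phospholipid", "negative"),
    "PG": ("phospholipid", "negative"),
    "PI": ("phospholipid", "negative"),
    "BMP": ("phospholipid", "negative"),
    "CL": ("phospholipid", "positive"),
    "SM": ("sphingolipid", "negative"),
    "Cer": ("sphingolipid", "negative"),
    "HexCer": ("sphingolipid", "negative"),
    "CoQ": ("neutral lipid", "positive"),
    "Ch/ChE": ("neutral lipid", "positive"),
    "DG": ("neutral lipid", "positive"),
    "TG": ("neutral lipid", "positive"),
    "fSFA": ("free fatty acid", "negative"),
    "fMUFA": ("free fatty acid", "negative"),
    "fPUFA": ("free fatty acid", "negative"),
    "Car": ("acylcarnitine", "positive"),
}

CATEGORIES = ("phospholipid", "sphingolipid", "neutral lipid",
              "free fatty acid", "acylcarnitine")

# longest token first so "HexCer" wins over "Cer" and "Ch/ChE" over nothing
_CLASS_TOKENS = sorted(CLASS_INFO, key=len, reverse=True)

_CD_RE = re.compile(r"^(\d+):(\d+)$")
_ACYL_RE = re.compile(r"^(d?)(\d+):(\d+)([ep]?)$")


@dataclass(frozen=True)
class FattyAcyl:
    """One acyl (or sphingoid-base) chain of a lipid."""

    carbons: int
    double_bonds: int
    linkage: Linkage = Linkage.ESTER

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double bond count must be >= 0")

    @property
    def key(self) -> str:
        """carbons:double_bonds label used for side-chain matching (16:0p -> 16:0)."""
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        prefix = "d" if self.linkage is Linkage.SPHINGOID else ""
        suffix = {"ether": "e", "plasmalogen": "p"}.get(self.linkage.value, "")
        return f"{prefix}{self.carbons}:{self.double_bonds}{suffix}"


ChainSet = tuple[FattyAcyl, ...]


@dataclass(frozen=True)
class LipidSpecies:
    """One catalogued lipid molecule."""

    name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether_flag: bool = False
    isomer_label: str | None = None   # None, "a" or "b"
    chain_assignments: tuple[ChainSet, ...] = ()   # empty = n.d.

    @property
    def category(self) -> str:
        return CLASS_INFO[self.lipid_class][0]

    @property
    def ion_mode(self) -> str:
        return CLASS_INFO[self.lipid_class][1]

    def with_chains(self, chains: Sequence[ChainSet]) -> "LipidSpecies":
        return replace(self, chain_assignments=tuple(tuple(c) for c in chains))


def parse_species_name(name: str) -> LipidSpecies:
    """Parse a shorthand species name; chain assignments are left unset.

    Grammar: ``<total C>:<total DB>`` + optional ``e/p`` + class token +
    optional ``-a``/``-b`` isomer suffix.
    """
    if not name:
        raise ParseError("empty species name")
    rest = name
    isomer: str | None = None
    if rest.endswith(("-a", "-b")):
        isomer = rest[-1]
        rest = rest[:-2]
    lipid_class = None
    for token in _CLASS_TOKENS:
        if rest.endswith(token):
            lipid_class = token
            rest = rest[: -len(token)]
            break
    if lipid_class is None:
        raise ParseError(f"unknown class token in {name!r}")
    ether = False
    if rest.endswith("e/p"):
        ether = True
        rest = rest[:-3]
    m = _CD_RE.match(rest)
    if m is None:
        raise ParseError(f"malformed carbon:double-bond field {rest!r} in {name!r}")
    return LipidSpecies(
        name=name,
        lipid_class=lipid_class,
        total_carbons=int(m.group(1)),
        total_double_bonds=int(m.group(2)),
        ether_flag=ether,
        isomer_label=isomer,
    )


def format_species_name(sp: LipidSpecies) -> str:
    """Inverse of :func:`parse_species_name` (round-trips every catalogued name)."""
    s = f"{sp.total_carbons}:{sp.total_double_bonds}"
    if sp.ether_flag:
        s += "e/p"
    s += sp.lipid_class
    if sp.isomer_label:
        s += f"-{sp.isomer_label}"
    return s


def parse_acyl(token: str) -> FattyAcyl:
    m = _ACYL_RE.match(token)
    if m is None:
        raise ParseError(f"malformed acyl token {token!r}")
    d, carbons, dbs, ep = m.groups()
    if d and ep:
        raise ParseError(f"acyl token {token!r} mixes sphingoid and ether marks")
    if d:
        linkage = Linkage.SPHINGOID
    elif ep == "e":
        linkage = Linkage.ETHER
    elif ep == "p":
        linkage = Linkage.PLASMALOGEN
    else:
        linkage = Linkage.ESTER
    return FattyAcyl(int(carbons), int(dbs), linkage)


def parse_chain_assignment(text: str) -> tuple[ChainSet, ...]:
    """Parse a chain-assignment string into alternative chain sets.

    ``"16:0/22:6"`` gives one alternative; ``"14:0/18:2 16:1/16:1"`` two;
    ``"n.d."`` (not determined) gives no alternatives at all.
    """
    text = text.strip()
    if not text or text in {"n.d.", "nd", "n.d"}:
        return ()
    alternatives = []
    for alt in text.split():
        alternatives.append(tuple(parse_acyl(tok) for tok in alt.split("/")))
    return tuple(alternatives)


def format_chain_assignment(chains: Sequence[ChainSet]) -> str:
    if not chains:
        return "n.d."
    return " ".join("/".join(str(a) for a in alt) for alt in chains)


# ---------------------------------------------------------------------------
# catalogue container

@dataclass
class LipidCatalogue:
    """Ordered, name-unique collection of :class:`LipidSpecies`."""

    species: list[LipidSpecies] = field(default_factory=list)
    #: free-text provenance per species name (e.g. "placeholder")
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [sp.name for sp in self.species]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate species names in catalogue: {dupes}")
        self._by_name = {sp.name: sp for sp in self.species}

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[LipidSpecies]:
        return iter(self.species)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> LipidSpecies:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in catalogue") from None

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species:
            seen.setdefault(sp.lipid_class, None)
        return list(seen)

    def species_in_class(self, lipid_class: str) -> list[LipidSpecies]:
        if lipid_class not in CLASS_INFO:
            raise KeyError(f"unknown lipid class {lipid_class!r}")
        return [sp for sp in self.species if sp.lipid_class == lipid_class]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "LipidCatalogue":
        species, sources = [], {}
        for rec in records:
            sp = parse_species_name(rec["name"])
            if rec.get("class") and rec["class"] != sp.lipid_class:
                raise ParseError(
                    f"{sp.name}: class column {rec['class']!r} disagrees with "
                    f"parsed class {sp.lipid_class!r}")
            if rec.get("ion_mode") and rec["ion_mode"] != sp.ion_mode:
                raise ParseError(
                    f"{sp.name}: ion_mode column {rec['ion_mode']!r} disagrees "
                    f"with class default {sp.ion_mode!r}")
            sp = sp.with_chains(parse_chain_assignment(rec.get("chains", "n.d.")))
            species.append(sp)
            if rec.get("source"):
                sources[sp.name] = rec["source"]
        return cls(species, sources)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LipidCatalogue":
        from . import io as _io
        rows, header = _io.read_tsv_rows(path)
        required = {"name", "class", "ion_mode", "chains"}
        if not required.issubset(header):
            raise ParseError(
                f"catalogue file {path} missing columns {sorted(required - set(header))}")
        return cls.from_records(dict(zip(header, row)) for row in rows)

    def to_tsv(self, path: str | Path) -> None:
        from . import io as _io
        rows = [
            [sp.name, sp.lipid_class, sp.ion_mode,
             format_chain_assignment(sp.chain_assignments),
             self.sources.get(sp.name, "")]
            for sp in self.species
        ]
        _io.write_tsv_rows(path, ["name", "class", "ion_mode", "chains", "source"], rows)


def reference_catalogue() -> LipidCatalogue:
    """The packaged 250-species mouse liver catalogue.

    The PC and PE panels (62 species) carry measured chain assignments; a
    handful of other species are anchored to reported molecules (42:1SM,
    38:1Cer, 38:4PI, 48:0TG, ...); the remainder are structurally valid
    placeholders flagged ``source=placeholder``.
    """
    path = resources.files("nashlipidomics") / "data" / "reference_catalogue.tsv"
    with resources.as_file(path) as p:
        return LipidCatalogue.from_tsv(p)


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ValidationIssue:
    species: str
    check: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    n_checked: int = 0
    n_chain_sets_checked: int = 0

    @property
    def ok(self) -> bool:
        return not self.issues

    def issues_for(self, name: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.species == name]


def _chain_set_totals(chains: ChainSet) -> tuple[int, int]:
    """Shorthand (carbons, double bonds) implied by one chain set.

    Ether linkages add 0 to the double-bond total, plasmalogen (vinyl-ether)
    linkages add 1 on top of the chain's own printed double bonds.
    """
    carbons = sum(a.carbons for a in chains)
    dbs = sum(a.double_bonds for a in chains)
    dbs += sum(1 for a in chains if a.linkage is Linkage.PLASMALOGEN)
    return carbons, dbs


def validate_catalogue(cat: LipidCatalogue) -> ValidationReport:
    """Consistency report: chain accounting, class/ion-mode agreement, duplicates.

    Carbon and double-bond sums are checked for every determined chain set
    that does not contain a sphingoid base; sphingolipid shorthand totals in
    this dialect do not always equal the base+N-acyl sum (e.g. 38:1Cer is
    reported as d18:1/16:0), so those sets are exempt from the sum check.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for sp in cat:
        report.n_checked += 1
        if sp.name in seen:
            report.issues.append(ValidationIssue(sp.name, "duplicate", "duplicate name"))
        seen.add(sp.name)
        if sp.lipid_class not in CLASS_INFO:
            report.issues.append(ValidationIssue(sp.name, "class", f"unknown class {sp.lipid_class!r}"))
            continue
        for chains in sp.chain_assignments:
            if any(a.linkage is Linkage.SPHINGOID for a in chains):
                continue
            report.n_chain_sets_checked += 1
            carbons, dbs = _chain_set_totals(chains)
            if carbons != sp.total_carbons:
                report.issues.append(ValidationIssue(
                    sp.name, "carbon-sum",
                    f"chains {format_chain_assignment([chains])} sum to "
                    f"{carbons} C, name says {sp.total_carbons}"))
            if dbs != sp.total_double_bonds:
                report.issues.append(ValidationIssue(
                    sp.name, "double-bond-sum",
                    f"chains {format_chain_assignment([chains])} imply {dbs} "
                    f"double bonds, name says {sp.total_double_bonds}"))
    return report


def class_counts(cat: LipidCatalogue) -> tuple[dict[str, int], dict[str, int]]:
    """(per-class species counts, per-category totals) over the catalogue."""
    by_class = Counter(sp.lipid_class for sp in cat)
    by_category = Counter(sp.category for sp in cat)
    return dict(by_class), dict(by_category)
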