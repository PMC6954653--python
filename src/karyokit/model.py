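"""Event-based karyotype model.

A karyotype is represented the way cytogenetic nomenclature does: a base
complement (46,XX / 46,XY / 46,XN and their haploid/triploid/tetraploid
analogues) plus an ordered list of interpretative change events.  Events are
the changes that *could have* produced the observed complement — an
edit-distance reading, not a history.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

from .band_map import (
    BandLabel,
    BandMap,
    ChromosomeName,
    DomainError,
    UNKNOWN_SEX,
)


class EventKind(enum.Enum):
    """The closed set of ISCN change events."""

    ADDITION = ("add", "Addition")
    DELETION = ("del", "Deletion")
    DERIVATIVE = ("der", "Derivative Chromosome")
    DICENTRIC = ("dic", "Dicentric Chromosome")
    DUPLICATION = ("dup", "Duplication")
    FISSION = ("fis", "Fission")
    FRAGILE_SITE = ("fra", "Fragile Site")
    HSR = ("hsr", "Homogeneously Staining Region")
    INSERTION = ("ins", "Insertion")
    INVERSION = ("inv", "Inversion")
    ISOCHROMOSOME = ("i", "Isochromosome")
    MARKER = ("mar", "Marker Chromosome")
    NEOCENTROMERE = ("neo", "Neocentromere")
    QUADRUPLICATION = ("qdp", "Quadruplication")
    RING = ("r", "Ring Chromosome")
    TELOMERIC_ASSOCIATION = ("tas", "Telomeric Association")
    TRANSLOCATION = ("t", "Translocation")
    TRICENTRIC = ("trc", "Tricentric Chromosome")
    TRIPLICATION = ("trp", "Triplication")

    def __init__(self, abbreviation: str, display_name: str):
        self.abbreviation = abbreviation
        self.display_name = display_name

    @classmethod
    def from_abbreviation(cls, abbr: str) -> "EventKind":
        for kind in cls:
            if kind.abbreviation == abbr:
                return kind
        raise KeyError(abbr)


#: chromosome-count change per event occurrence (ISCN convention; the
#: whole-chromosome gain/loss signs come from the +/- prefix itself)
COUNT_DELTA = {
    EventKind.FISSION: +1,
    EventKind.DICENTRIC: -1,
    EventKind.TELOMERIC_ASSOCIATION: -1,
    EventKind.TRICENTRIC: -2,
    EventKind.MARKER: +1,
}

#: kinds whose affected region is the inclusive band interval between two
#: breakpoints on one chromosome
INTERVAL_KINDS = {
    EventKind.DELETION,
    EventKind.DUPLICATION,
    EventKind.TRIPLICATION,
    EventKind.QUADRUPLICATION,
    EventKind.INVERSION,
}


class Level(enum.Enum):
    CHROMOSOME = "chromosome"
    BAND = "band"


@dataclass(frozen=True)
class Event:
    """One ISCN change: kind, targets, breakpoints, multiplicity.

    ``delta`` is +1/-1 for whole-chromosome gain/loss (the ISCN +/- prefix)
    and 0 for structural events, whose count effect comes from their kind.
    """

    kind: EventKind
    level: Level
    chromosomes: tuple[ChromosomeName, ...] = ()
    breakpoints: tuple[BandLabel, ...] = ()
    multiplicity: int = 1
    delta: int = 0
    constituents: tuple["Event", ...] = ()  # der only

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be positive")
        if self.level is Level.CHROMOSOME and self.breakpoints:
            raise ValueError("chromosome-level events carry no breakpoints")
        if self.level is Level.BAND and not self.breakpoints:
            raise ValueError("band-level events need at least one breakpoint")
        if not 0 <= len(self.chromosomes) <= 3:
            raise ValueError("events target 0-3 chromosomes")
        for bp in self.breakpoints:
            if bp.chromosome not in self.chromosomes:
                raise ValueError(f"breakpoint {bp} not on a target chromosome")

    @property
    def count_delta(self) -> int:
        if self.kind in COUNT_DELTA:
            base = COUNT_DELTA[self.kind]
        elif self.level is Level.CHROMOSOME:
            base = self.delta
        else:
            base = 0
        return base * self.multiplicity

    def copy_delta(self, c: ChromosomeName) -> int:
        """Per-chromosome copy-number change (sums to count_delta for
        chromosome-carrying events; markers have no chromosome identity)."""
        if self.kind is EventKind.MARKER:
            return 0
        d = 0
        if self.level is Level.CHROMOSOME:
            if self.chromosomes and self.chromosomes[0] == c:
                d = self.delta
        elif self.kind is EventKind.FISSION:
            d = +1 if self.chromosomes[0] == c else 0
        elif self.kind in (EventKind.DICENTRIC, EventKind.TELOMERIC_ASSOCIATION):
            d = -1 if self.chromosomes[0] == c else 0
        elif self.kind is EventKind.TRICENTRIC:
            d = -sum(1 for ch in self.chromosomes[:2] if ch == c)
        return d * self.multiplicity


@dataclass(frozen=True)
class BaseKaryotype:
    """A notional starting complement: ploidy plus sex-chromosome string."""

    ploidy: int  # 1..4
    sex_complement: str  # e.g. "XY", "XX", "XN", "XXY"

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2, 3, 4):
            raise ValueError("ploidy must be 1-4")
        if len(self.sex_complement) != self.ploidy:
            raise ValueError("sex complement length must equal ploidy")
        if not set(self.sex_complement) <= {"X", "Y", "N"}:
            raise ValueError("sex complement may contain only X, Y, N")

    @property
    def name(self) -> str:
        return f"k{23 * self.ploidy}_{self.sex_complement}"

    def sex_copies(self, label: str) -> int:
        return self.sex_complement.count(label)


K46_XX = BaseKaryotype(2, "XX")
K46_XY = BaseKaryotype(2, "XY")
K46_XN = BaseKaryotype(2, "XN")


def base_count(base: BaseKaryotype) -> int:
    """Total chromosomes in an unmodified base: 23 per haploid set."""
    return 23 * base.ploidy


@dataclass(frozen=True)
class Karyotype:
    base: BaseKaryotype
    events: tuple[Event, ...] = ()
    declared_total: Optional[int] = None

    def with_declared_total(self, total: int) -> "Karyotype":
        return replace(self, declared_total=total)


def chromosome_count(k: Karyotype) -> int:
    return base_count(k.base) + sum(e.count_delta for e in k.events)


def marker_count(k: Karyotype) -> int:
    return sum(e.multiplicity for e in k.events if e.kind is EventKind.MARKER)


def copy_number(k: Karyotype, c: ChromosomeName | str) -> int:
    """Copies of chromosome *c*: base complement plus gains minus losses."""
    if isinstance(c, str):
        c = ChromosomeName(c)
    if c.is_autosome:
        baseline = k.base.ploidy
    else:
        baseline = k.base.sex_copies(c.label)
    return baseline + sum(e.copy_delta(c) for e in k.events)


def affected_bands(e: Event, band_map: BandMap) -> set[BandLabel]:
    """Bands a structural event touches.

    Interval kinds with two breakpoints on one chromosome cover the whole
    inclusive interval; a one-breakpoint (terminal) deletion runs to the
    telomere of its arm; an isochromosome covers its whole arm; everything
    else touches exactly its breakpoint bands.
    """
    if e.level is not Level.BAND:
        raise DomainError("chromosome-level events have no affected bands")
    bps = e.breakpoints
    if (
        e.kind in INTERVAL_KINDS
        and len(bps) == 2
        and bps[0].chromosome == bps[1].chromosome
    ):
        return set(band_map.bands_between(bps[0], bps[1]))
    if e.kind is EventKind.DELETION and len(bps) == 1:
        tel = band_map.terminal_band(bps[0].chromosome, bps[0].arm)
        return set(band_map.bands_between(bps[0], tel))
    if e.kind is EventKind.ISOCHROMOSOME:
        return set(band_map.arm_bands(bps[0].chromosome, bps[0].arm))
    if e.kind is EventKind.DERIVATIVE:
        out: set[BandLabel] = set(bps)
        for sub in e.constituents:
            out |= affected_bands(sub, band_map)
        return out
    return set(bps)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    location: str  # what the finding is about
    message: str


def validate(k: Karyotype, band_map: BandMap) -> list[Finding]:
    """Structural findings for a karyotype; empty iff it is consistent."""
    findings: list[Finding] = []
    for i, e in enumerate(k.events):
        where = f"event[{i}]"
        for bp in e.breakpoints:
            if not band_map.band_exists(str(bp)):
                findings.append(Finding("error", where, f"unknown band {bp}"))
            if bp.chromosome not in e.chromosomes:
                findings.append(
                    Finding("error", where, f"breakpoint {bp} off the event's chromosomes")
                )
    for c in band_map.chromosomes:
        n = copy_number(k, c)
        if n < 0:
            findings.append(
                Finding("error", f"chromosome {c}", f"copy number {n} is negative")
            )
    if k.declared_total is not None:
        computed = chromosome_count(k)
        if computed != k.declared_total:
            findings.append(
                Finding(
                    "error",
                    "total",
                    f"declared total {k.declared_total} but events compute {computed}",
                )
            )
    return findings
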