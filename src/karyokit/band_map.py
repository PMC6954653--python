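"""Chromosome band partonomy with linear order and resolution levels.

The 24 human chromosome types (1-22, X, Y) are modelled as an ordered
partonomy: each chromosome has a p and a q arm, each arm carries cytogenetic
bands (e.g. ``1p36``), and bands may carry dotted sub-bands that become
visible only at finer idiogram resolutions (e.g. ``17q21.31``).  Band numbers
increase away from the centromere, so the pter->qter traversal runs down the
p-arm designations and up the q-arm ones.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

RESOLUTION_LEVELS = (300, 400, 550, 700, 850)

CHROMOSOME_LABELS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: pseudo-label for an unknown sex chromosome (the "N" of a 46,XN base)
UNKNOWN_SEX = "N"


class BandMapError(ValueError):
    """Malformed band table."""


class UnknownBandError(KeyError):
    """A band label that names no entry in the map."""


class DomainError(ValueError):
    """Operands violate an operation's domain (e.g. bands on different chromosomes)."""


class ResolutionError(ValueError):
    """A band is not visible at the requested resolution and cannot be expanded."""


@dataclass(frozen=True)
class ChromosomeName:
    label: str

    def __post_init__(self) -> None:
        if self.label not in CHROMOSOME_LABELS and self.label != UNKNOWN_SEX:
            raise ValueError(f"not a human chromosome: {self.label!r}")

    @property
    def is_autosome(self) -> bool:
        return self.label.isdigit()

    @property
    def is_sex_chromosome(self) -> bool:
        return self.label in ("X", "Y", UNKNOWN_SEX)

    def __str__(self) -> str:
        return self.label

    def sort_key(self) -> int:
        order = CHROMOSOME_LABELS + (UNKNOWN_SEX,)
        return order.index(self.label)


_BAND_RE = re.compile(r"^(\d{1,2}|X|Y)(p|q)(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class BandLabel:
    chromosome: ChromosomeName
    arm: str  # "p" | "q"
    designation: str  # "36", "21.31", ...

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")
        if not re.fullmatch(r"\d+(\.\d+)?", self.designation):
            raise ValueError(f"bad band designation {self.designation!r}")

    @classmethod
    def parse(cls, text: str) -> "BandLabel":
        m = _BAND_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a band label: {text!r}")
        return cls(ChromosomeName(m.group(1)), m.group(2), m.group(3))

    @property
    def parent_designation(self) -> str | None:
        """Undotted prefix for dotted bands (``21.31`` -> ``21``), else None."""
        if "." in self.designation:
            return self.designation.split(".", 1)[0]
        return None

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}{self.designation}"


@dataclass
class BandEntry:
    label: BandLabel
    parent: BandLabel | None  # None: direct child of the arm
    min_resolution: int  # coarsest level at which the band is visible
    order_index: int  # pter->qter position within the chromosome (finest traversal)
    children: list[BandLabel] = field(default_factory=list)

    @property
    def resolutions(self) -> frozenset[int]:
        """Visibility is cumulative: visible at its level and every finer one."""
        return frozenset(r for r in RESOLUTION_LEVELS if r >= self.min_resolution)


class BandMap:
    """Validated band partonomy supporting existence, order and interval queries."""

    def __init__(self, entries: Iterable[BandEntry]):
        self.entries: list[BandEntry] = list(entries)
        self._by_label: dict[str, BandEntry] = {}
        self._per_chromosome: dict[str, list[BandEntry]] = {c: [] for c in CHROMOSOME_LABELS}
        for e in self.entries:
            key = str(e.label)
            if key in self._by_label:
                raise BandMapError(f"duplicate band label {key}")
            self._by_label[key] = e
            self._per_chromosome[e.label.chromosome.label].append(e)
        self._validate()

    # -- construction ---------------------------------------------------

    def _validate(self) -> None:
        for chrom, entries in self._per_chromosome.items():
            if not entries:
                raise BandMapError(f"chromosome {chrom} has no bands")
            arms = {e.label.arm for e in entries}
            if arms != {"p", "q"}:
                raise BandMapError(f"chromosome {chrom} must have p and q bands, has {arms}")
            idx = [e.order_index for e in entries]
            if idx != sorted(idx) or len(set(idx)) != len(idx):
                raise BandMapError(f"chromosome {chrom}: order indices not strictly increasing")
            # all p before all q in the pter->qter traversal
            last_p = max(e.order_index for e in entries if e.label.arm == "p")
            first_q = min(e.order_index for e in entries if e.label.arm == "q")
            if last_p > first_q:
                raise BandMapError(f"chromosome {chrom}: p-arm bands must precede q-arm bands")
        for e in self.entries:
            pd = e.label.parent_designation
            if pd is not None:
                anc = f"{e.label.chromosome}{e.label.arm}{pd}"
                if anc not in self._by_label:
                    raise BandMapError(f"dotted band {e.label} lacks ancestor {anc}")

    @property
    def chromosomes(self) -> list[ChromosomeName]:
        return [ChromosomeName(c) for c in CHROMOSOME_LABELS]

    # -- queries ---------------------------------------------------------

    def entry(self, band: BandLabel | str) -> BandEntry:
        key = str(band) if isinstance(band, BandLabel) else band.strip()
        try:
            return self._by_label[key]
        except KeyError:
            raise UnknownBandError(f"unknown band {key!r}") from None

    def band_exists(self, label: str) -> bool:
        """True iff the text canonicalizes to a chromosome, an arm, or a band."""
        text = label.strip()
        if text in CHROMOSOME_LABELS:
            return True
        m = re.fullmatch(r"(\d{1,2}|X|Y)(p|q)", text)
        if m and m.group(1) in CHROMOSOME_LABELS:
            return True
        try:
            return str(BandLabel.parse(text)) in self._by_label
        except ValueError:
            return False

    def bands_of(self, chromosome: ChromosomeName | str, arm: str | None = None) -> list[BandEntry]:
        label = chromosome.label if isinstance(chromosome, ChromosomeName) else str(chromosome)
        entries = self._per_chromosome.get(label, [])
        if arm is not None:
            entries = [e for e in entries if e.label.arm == arm]
        return list(entries)

    def sub_bands(self, band: BandLabel | str) -> list[BandLabel]:
        """All bands whose parent chain includes *band*, in traversal order."""
        target = self.entry(band)
        out = []
        for e in self._per_chromosome[target.label.chromosome.label]:
            p = e.parent
            while p is not None:
                if p == target.label:
                    out.append(e.label)
                    break
                p = self.entry(p).parent
        return out

    def seen_at_resolution(self, band: BandLabel | str, res: int) -> bool:
        if res not in RESOLUTION_LEVELS:
            raise ValueError(f"not a resolution level: {res}")
        return res in self.entry(band).resolutions

    def compare_bands(self, a: BandLabel | str, b: BandLabel | str) -> int:
        """-1/0/+1 for *a* before/equal/after *b* in pter->qter order."""
        ea, eb = self.entry(a), self.entry(b)
        if ea.label.chromosome != eb.label.chromosome:
            raise DomainError(f"bands {ea.label} and {eb.label} lie on different chromosomes")
        if ea.order_index == eb.order_index:
            return 0
        return -1 if ea.order_index < eb.order_index else 1

    def traversal(self, chromosome: ChromosomeName | str, res: int = 850) -> list[BandLabel]:
        """The linear pter->qter band sequence visible at resolution *res*.

        A band whose sub-bands are visible at *res* is replaced by them, so the
        sequence is a partition of the chromosome at that resolution.
        """
        out: list[BandLabel] = []
        for e in self.bands_of(chromosome):
            if e.min_resolution > res:
                continue
            visible_children = [c for c in e.children if self.entry(c).min_resolution <= res]
            if not visible_children:
                out.append(e.label)
        return out

    def bands_between(
        self, a: BandLabel | str, b: BandLabel | str, res: int = 850
    ) -> list[BandLabel]:
        """Inclusive ordered band interval between *a* and *b* at resolution *res*.

        Symmetric in its endpoints and may span the centromere.  An endpoint
        that is a parent band at *res* is expanded to its outermost visible
        descendant so the interval stays inclusive.
        """
        ea, eb = self.entry(a), self.entry(b)
        if ea.label.chromosome != eb.label.chromosome:
            raise DomainError(f"bands {ea.label} and {eb.label} lie on different chromosomes")
        if ea.order_index > eb.order_index:
            ea, eb = eb, ea
        seq = self.traversal(ea.label.chromosome, res)
        pos = {str(lbl): i for i, lbl in enumerate(seq)}

        def endpoint(e: BandEntry, last: bool) -> int:
            if str(e.label) in pos:
                return pos[str(e.label)]
            if e.min_resolution > res:
                raise ResolutionError(f"band {e.label} not visible at the {res}-band level")
            # parent band expanded at res: span all of its visible descendants
            desc = [pos[str(d)] for d in self.sub_bands(e.label) if str(d) in pos]
            if not desc:
                raise ResolutionError(f"band {e.label} has no visible form at {res}")
            return max(desc) if last else min(desc)

        lo, hi = endpoint(ea, last=False), endpoint(eb, last=True)
        return seq[lo : hi + 1]

    def arm_bands(self, chromosome: ChromosomeName | str, arm: str, res: int = 850) -> list[BandLabel]:
        """All bands of one arm at resolution *res*, pter->qter order."""
        return [lbl for lbl in self.traversal(chromosome, res) if lbl.arm == arm]

    def terminal_band(self, chromosome: ChromosomeName | str, arm: str, res: int = 850) -> BandLabel:
        """The telomeric band of an arm (first on p, last on q in traversal order)."""
        bands = self.arm_bands(chromosome, arm, res)
        return bands[0] if arm == "p" else bands[-1]


def load_band_map(source) -> BandMap:
    """Load a band table from TSV text, a path, or an open file.

    Columns: chromosome, arm, band, parent, resolutions (semicolon-separated);
    an empty parent means the band is a direct child of its arm.  Rows must be
    in pter->qter order per chromosome, each sub-band after its parent.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\t" not in text and "\n" not in text:
            with open(text, encoding="utf-8") as fh:
                text = fh.read()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"chromosome", "arm", "band", "parent", "resolutions"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise BandMapError(f"band table must have columns {sorted(required)}")

    entries: list[BandEntry] = []
    by_label: dict[str, BandEntry] = {}
    counters: dict[str, int] = {}
    for lineno, row in enumerate(reader, start=2):
        chrom = row["chromosome"].strip()
        if chrom not in CHROMOSOME_LABELS:
            raise BandMapError(f"line {lineno}: unknown chromosome {chrom!r}")
        label = BandLabel(ChromosomeName(chrom), row["arm"].strip(), row["band"].strip())
        if str(label) in by_label:
            raise BandMapError(f"line {lineno}: duplicate band label {label}")
        parent_txt = row["parent"].strip()
        parent = None
        if parent_txt:
            parent = BandLabel(label.chromosome, label.arm, parent_txt)
            if str(parent) not in by_label:
                raise BandMapError(f"line {lineno}: child {label} listed before parent {parent}")
        try:
            res_levels = sorted(int(r) for r in row["resolutions"].split(";") if r.strip())
        except ValueError:
            raise BandMapError(f"line {lineno}: bad resolutions {row['resolutions']!r}") from None
        if not res_levels or any(r not in RESOLUTION_LEVELS for r in res_levels):
            raise BandMapError(f"line {lineno}: resolutions must be among {RESOLUTION_LEVELS}")
        counters[chrom] = counters.get(chrom, -1) + 1
        entry = BandEntry(label, parent, min(res_levels), counters[chrom])
        entries.append(entry)
        by_label[str(label)] = entry
        if parent is not None:
            by_label[str(parent)].children.append(label)
    return BandMap(entries)


def default_band_map() -> BandMap:
    """The packaged ~400-band-level table (all 24 chromosomes)."""
    text = resources.files("karyokit.data").joinpath("bands_400.tsv").read_text("utf-8")
    return load_band_map(io.StringIO(text))
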