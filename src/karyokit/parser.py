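"""Parser for a well-defined subset of ISCN karyotype designations.

The accepted dialect covers single-clone designations: a chromosome total,
a sex designation over {X, Y, N}, then comma-separated change events — the
whole-chromosome gains/losses (``+21``, ``-Y``) and the structural event
abbreviations (``del``, ``t``, ``inv``, ...) with one or two chromosome
groups and band breakpoints, e.g. ``46,XY,del(15)(q11q12)`` or
``46,XY,t(2;5)(q21;q31)``.  Mosaic/composite clones ("/"), uncertainty
markers ("?") and approximate totals are rejected with an explicit
unsupported-dialect error rather than guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .band_map import BandLabel, BandMap, ChromosomeName, CHROMOSOME_LABELS, UNKNOWN_SEX
from .model import (
    BaseKaryotype,
    Event,
    EventKind,
    Karyotype,
    Level,
    chromosome_count,
)


class ParseError(ValueError):
    """The text is not in the supported ISCN dialect."""


class UnsupportedEventError(ParseError):
    """An event abbreviation outside the supported set."""


class ValidationError(ParseError):
    """Syntactically fine but names a chromosome/band that does not exist."""


class StructureError(ParseError):
    """Wrong arity: chromosome/breakpoint groups do not fit the event kind."""


class ConsistencyError(ParseError):
    """Declared chromosome total disagrees with the computed one."""


@dataclass(frozen=True)
class ParsedDesignation:
    declared_total: int
    sex_field: str
    raw_event_fields: tuple[str, ...]


_UNSUPPORTED = re.compile(r"[/?~]|idem|\bish\b")


def tokenize(iscn: str) -> ParsedDesignation:
    """Split an ISCN string on top-level commas into total, sex, event fields."""
    if not iscn or not iscn.strip():
        raise ParseError("empty ISCN string")
    text = iscn.strip()
    if _UNSUPPORTED.search(text):
        raise ParseError(
            f"unsupported ISCN dialect (mosaic/uncertain notation) in {iscn!r}"
        )
    fields: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced parentheses in {iscn!r}")
        if ch == "," and depth == 0:
            fields.append("".join(current).strip())
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise ParseError(f"unbalanced parentheses in {iscn!r}")
    fields.append("".join(current).strip())
    if len(fields) < 2:
        raise ParseError(f"expected at least total and sex fields in {iscn!r}")
    total_txt = fields[0].replace(" ", "")
    if not total_txt.isdigit():
        raise ParseError(f"chromosome total {fields[0]!r} is not an integer")
    sex = fields[1].replace(" ", "")
    if not sex or not set(sex) <= {"X", "Y", "N"}:
        raise ParseError(f"sex designation {fields[1]!r} must be over X/Y/N")
    events = tuple(f.replace(" ", "") for f in fields[2:] if f.strip())
    return ParsedDesignation(int(total_txt), sex, events)


# arity table: kind -> (n_chromosomes, n_breakpoints accepted)
_ARITY: dict[EventKind, tuple[tuple[int, ...], tuple[int, ...]]] = {
    EventKind.ADDITION: ((1,), (1,)),
    EventKind.DELETION: ((1,), (1, 2)),
    EventKind.DICENTRIC: ((2,), (2,)),
    EventKind.DUPLICATION: ((1,), (2,)),
    EventKind.FISSION: ((1,), (1,)),
    EventKind.FRAGILE_SITE: ((1,), (1,)),
    EventKind.HSR: ((1,), (1,)),
    EventKind.INSERTION: ((1, 2), (3,)),
    EventKind.INVERSION: ((1,), (2,)),
    EventKind.ISOCHROMOSOME: ((1,), (1,)),
    EventKind.NEOCENTROMERE: ((1,), (1,)),
    EventKind.QUADRUPLICATION: ((1,), (2,)),
    EventKind.RING: ((1,), (2,)),
    EventKind.TELOMERIC_ASSOCIATION: ((2,), (2,)),
    EventKind.TRANSLOCATION: ((2,), (2,)),
    EventKind.TRICENTRIC: ((3,), (3,)),
    EventKind.TRIPLICATION: ((1,), (2,)),
}

_GROUP_RE = re.compile(r"\(([^()]*)\)")
_BP_RE = re.compile(r"[pq]\d+(?:\.\d+)?")
# longest abbreviations first so "inv" is not read as "i"
_ABBRS = sorted((k.abbreviation for k in EventKind), key=len, reverse=True)


def _parse_breakpoint(token: str, chromosome: ChromosomeName, band_map: BandMap) -> BandLabel:
    label = f"{chromosome}{token}"
    if not band_map.band_exists(label):
        raise ValidationError(f"band {label!r} does not exist")
    return BandLabel.parse(label)


def parse_event(field: str, band_map: BandMap) -> Event:
    """Parse one raw event token into an Event, validating every band."""
    field = field.replace(" ", "")
    if not field:
        raise ParseError("empty event field")

    # whole-chromosome gain/loss: +21, -Y
    m = re.fullmatch(r"([+-])(\d{1,2}|X|Y)", field)
    if m:
        sign = +1 if m.group(1) == "+" else -1
        chrom = m.group(2)
        if chrom not in CHROMOSOME_LABELS:
            raise ValidationError(f"chromosome {chrom!r} does not exist")
        kind = EventKind.ADDITION if sign > 0 else EventKind.DELETION
        return Event(kind, Level.CHROMOSOME, (ChromosomeName(chrom),), delta=sign)

    # markers are chromosome-less: mar / +mar
    if field in ("mar", "+mar"):
        return Event(EventKind.MARKER, Level.CHROMOSOME)

    body = field[1:] if field[0] == "+" else field
    for abbr in _ABBRS:
        if body.startswith(abbr + "("):
            break
    else:
        raise UnsupportedEventError(f"unknown event abbreviation in {field!r}")
    kind = EventKind.from_abbreviation(abbr)
    rest = body[len(abbr):]

    if kind is EventKind.DERIVATIVE:
        return _parse_derivative(rest, band_map)

    groups = _GROUP_RE.findall(rest)
    if _GROUP_RE.sub("", rest):
        raise StructureError(f"trailing text outside groups in {field!r}")
    if len(groups) != 2:
        raise StructureError(f"{abbr} needs a chromosome group and a breakpoint group")
    return _build_event(kind, groups[0], groups[1], field, band_map)


def _build_event(
    kind: EventKind, chrom_group: str, bp_group: str, field: str, band_map: BandMap
) -> Event:
    chrom_names = chrom_group.split(";")
    for c in chrom_names:
        if c not in CHROMOSOME_LABELS:
            raise ValidationError(f"chromosome {c!r} does not exist (in {field!r})")
    chroms = tuple(ChromosomeName(c) for c in chrom_names)

    n_chrom_ok, n_bp_ok = _ARITY[kind]
    if len(chroms) not in n_chrom_ok:
        raise StructureError(
            f"{kind.abbreviation} takes {n_chrom_ok} chromosome(s), got {len(chroms)}"
        )

    bp_parts = bp_group.split(";")
    if len(bp_parts) != len(chroms):
        raise StructureError(
            f"{kind.abbreviation}: {len(chroms)} chromosome(s) but "
            f"{len(bp_parts)} breakpoint group(s) in {field!r}"
        )
    breakpoints: list[BandLabel] = []
    for chrom, part in zip(chroms, bp_parts):
        tokens = _BP_RE.findall(part)
        if "".join(tokens) != part:
            raise StructureError(f"malformed breakpoint group {part!r} in {field!r}")
        for tok in tokens:
            breakpoints.append(_parse_breakpoint(tok, chrom, band_map))
    if len(breakpoints) not in n_bp_ok:
        raise StructureError(
            f"{kind.abbreviation} takes {n_bp_ok} breakpoint(s), got {len(breakpoints)}"
        )
    return Event(kind, Level.BAND, chroms, tuple(breakpoints))


def _parse_derivative(rest: str, band_map: BandMap) -> Event:
    """der(c) followed by the constituent events that define the derivative."""
    m = re.match(r"\((\d{1,2}|X|Y)\)", rest)
    if not m:
        raise StructureError(f"der needs a single chromosome group, got {rest!r}")
    chrom = ChromosomeName(m.group(1))
    tail = rest[m.end():]
    constituents: list[Event] = []
    # constituents are concatenated event specs: der(1)t(1;3)(p22;q13)
    pattern = re.compile(r"([a-z]+)(\([^()]*\))(\([^()]*\))?")
    pos = 0
    while pos < len(tail):
        cm = pattern.match(tail, pos)
        if not cm:
            raise StructureError(f"cannot read derivative constituents from {tail!r}")
        spec = cm.group(0)
        constituents.append(parse_event(spec, band_map))
        pos = cm.end()
    if not constituents:
        raise StructureError("der needs at least one constituent event")
    bps = tuple(bp for e in constituents for bp in e.breakpoints if bp.chromosome == chrom)
    if not bps:
        # anchor the derivative to its chromosome via the constituents' bands
        bps = tuple(e.breakpoints[0] for e in constituents if e.breakpoints)[:1]
    all_chroms = (chrom,) + tuple(
        c for e in constituents for c in e.chromosomes if c != chrom
    )
    # dedupe, preserve order, cap at 3 per the event model
    seen: list[ChromosomeName] = []
    for c in all_chroms:
        if c not in seen:
            seen.append(c)
    return Event(
        EventKind.DERIVATIVE,
        Level.BAND,
        tuple(seen[:3]),
        tuple(bp for bp in bps if bp.chromosome in seen[:3]),
        constituents=tuple(constituents),
    )


def _merge_duplicates(events: list[Event]) -> tuple[Event, ...]:
    """Identical repeated fields accumulate into one event's multiplicity."""
    merged: list[Event] = []
    for e in events:
        for i, prev in enumerate(merged):
            if (
                prev.kind == e.kind
                and prev.level == e.level
                and prev.chromosomes == e.chromosomes
                and prev.breakpoints == e.breakpoints
                and prev.delta == e.delta
                and prev.constituents == e.constituents
            ):
                merged[i] = Event(
                    prev.kind,
                    prev.level,
                    prev.chromosomes,
                    prev.breakpoints,
                    prev.multiplicity + e.multiplicity,
                    prev.delta,
                    prev.constituents,
                )
                break
        else:
            merged.append(e)
    return tuple(merged)


def _infer_base(parsed: ParsedDesignation, events: list[Event]) -> tuple[BaseKaryotype, list[Event]]:
    """Reconstruct the base complement the designation is derived from.

    The base must hold exactly `ploidy` sex chromosomes; explicit sex-chromosome
    gains/losses among the events are undone to recover it.  A shortfall that no
    event explains (e.g. 45,X) derives from an unknown sex chromosome — the base
    is padded with N and an implicit loss of that unknown chromosome is added.
    """
    explicit_delta = sum(e.count_delta for e in events)
    complement = list(parsed.sex_field)
    for e in events:
        if e.level is Level.CHROMOSOME and e.chromosomes and e.chromosomes[0].is_sex_chromosome:
            label = e.chromosomes[0].label
            for _ in range(e.multiplicity):
                if e.delta < 0:
                    complement.append(label)  # lost from base, so base had it
                elif e.delta > 0:
                    if label not in complement:
                        raise ConsistencyError(
                            f"gain of {label} but {label} absent from sex field "
                            f"{parsed.sex_field!r}"
                        )
                    complement.remove(label)

    # Each implicit sex-chromosome loss/gain also moves the total by one, so
    # the ploidy solves 22*p = declared - explicit_delta - |complement|.
    numerator = parsed.declared_total - explicit_delta - len(complement)
    if numerator % 22 != 0 or numerator // 22 not in (1, 2, 3, 4):
        raise ConsistencyError(
            f"declared total {parsed.declared_total} fits no base of ploidy 1-4 "
            f"given sex field {parsed.sex_field!r} and the stated events"
        )
    ploidy = numerator // 22

    implicit: list[Event] = []
    while len(complement) < ploidy:
        complement.append(UNKNOWN_SEX)
        implicit.append(
            Event(EventKind.DELETION, Level.CHROMOSOME, (ChromosomeName(UNKNOWN_SEX),), delta=-1)
        )
    while len(complement) > ploidy:
        # the unexplained gain duplicates a letter already present, so the
        # base keeps one of each observed kind (47,XXY derives from 46,XY)
        extra = next(
            (l for l in reversed(complement) if complement.count(l) > 1), complement[-1]
        )
        complement.remove(extra)
        implicit.append(
            Event(EventKind.ADDITION, Level.CHROMOSOME, (ChromosomeName(extra),), delta=+1)
        )
    complement.sort(key="XYN".index)
    return BaseKaryotype(ploidy, "".join(complement)), implicit


def parse(iscn: str, band_map: BandMap) -> Karyotype:
    """Parse an ISCN designation into a Karyotype, checking the declared total."""
    parsed = tokenize(iscn)
    events = [parse_event(f, band_map) for f in parsed.raw_event_fields]
    base, implicit = _infer_base(parsed, events)
    k = Karyotype(base, _merge_duplicates(events + implicit), parsed.declared_total)
    computed = chromosome_count(k)
    if computed != parsed.declared_total:
        raise ConsistencyError(
            f"declared total {parsed.declared_total} but events compute {computed}"
        )
    return k


_KIND_ORDER = [k.abbreviation for k in EventKind]


def _event_sort_key(e: Event):
    chrom = e.chromosomes[0].sort_key() if e.chromosomes else 99
    return (chrom, _KIND_ORDER.index(e.kind.abbreviation))


def format_event(e: Event) -> str:
    if e.kind is EventKind.MARKER:
        return "+mar"
    if e.level is Level.CHROMOSOME:
        sign = "+" if e.delta > 0 else "-"
        return f"{sign}{e.chromosomes[0]}"
    if e.kind is EventKind.DERIVATIVE:
        return f"der({e.chromosomes[0]})" + "".join(format_event(c) for c in e.constituents)
    chrom_group = ";".join(str(c) for c in e.chromosomes)
    if len(e.chromosomes) == 1:
        bp_group = "".join(f"{bp.arm}{bp.designation}" for bp in e.breakpoints)
    else:
        parts = []
        for c in e.chromosomes:
            parts.append(
                "".join(f"{bp.arm}{bp.designation}" for bp in e.breakpoints if bp.chromosome == c)
            )
        bp_group = ";".join(parts)
    return f"{e.kind.abbreviation}({chrom_group})({bp_group})"


def canonical_iscn(k: Karyotype) -> str:
    """Emit the normalized designation: no spaces, events sorted, N's implicit."""
    total = chromosome_count(k)
    observed = list(k.base.sex_complement)
    visible_events: list[Event] = []
    for e in k.events:
        is_sex_numeric = (
            e.level is Level.CHROMOSOME
            and e.chromosomes
            and e.chromosomes[0].is_sex_chromosome
        )
        if is_sex_numeric:
            label = e.chromosomes[0].label
            for _ in range(e.multiplicity):
                if e.delta < 0 and label in observed:
                    observed.remove(label)
                elif e.delta > 0:
                    observed.append(label)
            if label == UNKNOWN_SEX:
                continue  # implicit: re-inferred from the totals on re-parse
        visible_events.append(e)
    observed = [c for c in observed if c != UNKNOWN_SEX] or ["N"]
    observed.sort(key="XYN".index)
    parts = [str(total), "".join(observed)]
    for e in sorted(visible_events, key=_event_sort_key):
        parts.extend([format_event(e)] * e.multiplicity)
    return ",".join(parts)
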