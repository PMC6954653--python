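"""Seeded random-karyotype generator.

Produces valid, parseable karyotypes for property testing and for the
band-order scaling experiment.  Events are drawn per karyotype: each slot is
numerical (a whole-chromosome gain/loss) with probability
``numerical_event_probability``, otherwise a structural kind drawn from
``event_kind_weights`` with breakpoints sampled from bands that exist in the
map.  Every output validates cleanly and round-trips through the parser.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import IO

from .band_map import BandMap, ChromosomeName, CHROMOSOME_LABELS
from .model import (
    BaseKaryotype,
    Event,
    EventKind,
    Karyotype,
    Level,
    chromosome_count,
    copy_number,
    validate,
)


class ConfigError(ValueError):
    pass


#: structural kinds the generator draws from (band-level forms of the event
#: table; markers have no band-level form and are never generated)
GENERATABLE_KINDS = (
    EventKind.ADDITION,
    EventKind.DELETION,
    EventKind.DERIVATIVE,
    EventKind.DICENTRIC,
    EventKind.DUPLICATION,
    EventKind.FISSION,
    EventKind.FRAGILE_SITE,
    EventKind.HSR,
    EventKind.INSERTION,
    EventKind.INVERSION,
    EventKind.ISOCHROMOSOME,
    EventKind.NEOCENTROMERE,
    EventKind.QUADRUPLICATION,
    EventKind.RING,
    EventKind.TELOMERIC_ASSOCIATION,
    EventKind.TRANSLOCATION,
    EventKind.TRICENTRIC,
    EventKind.TRIPLICATION,
)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n: int = 100
    event_kind_weights: dict[EventKind, float] = field(
        default_factory=lambda: {k: 1.0 for k in GENERATABLE_KINDS}
    )
    max_events_per_karyotype: int = 3
    numerical_event_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1 or self.max_events_per_karyotype < 1:
            raise ConfigError("n and max_events_per_karyotype must be positive")
        if not 0 <= self.numerical_event_probability <= 1:
            raise ConfigError("numerical_event_probability must be in [0, 1]")
        if not self.event_kind_weights or all(
            w <= 0 for w in self.event_kind_weights.values()
        ):
            raise ConfigError("at least one event kind weight must be positive")
        if any(w < 0 for w in self.event_kind_weights.values()):
            raise ConfigError("weights must be non-negative")


def _sample_band(rng: random.Random, band_map: BandMap, chrom: str, arm: str | None = None):
    bands = band_map.traversal(chrom)
    if arm is not None:
        bands = [b for b in bands if b.arm == arm]
    return rng.choice(bands)


def _sample_interval(rng: random.Random, band_map: BandMap, chrom: str):
    bands = band_map.traversal(chrom)
    i, j = sorted(rng.sample(range(len(bands)), 2)) if len(bands) > 1 else (0, 0)
    return bands[i], bands[j]


def _structural_event(rng: random.Random, kind: EventKind, band_map: BandMap) -> Event:
    chroms = list(CHROMOSOME_LABELS)
    if kind in (
        EventKind.DICENTRIC,
        EventKind.TELOMERIC_ASSOCIATION,
        EventKind.TRANSLOCATION,
    ):
        c1, c2 = rng.sample(chroms, 2)
        bps = (_sample_band(rng, band_map, c1), _sample_band(rng, band_map, c2))
        return Event(kind, Level.BAND, (ChromosomeName(c1), ChromosomeName(c2)), bps)
    if kind is EventKind.TRICENTRIC:
        cs = rng.sample(chroms, 3)
        bps = tuple(_sample_band(rng, band_map, c) for c in cs)
        return Event(kind, Level.BAND, tuple(ChromosomeName(c) for c in cs), bps)
    if kind is EventKind.INSERTION:
        c = rng.choice(chroms)
        b1 = _sample_band(rng, band_map, c)
        b2, b3 = _sample_interval(rng, band_map, c)
        return Event(kind, Level.BAND, (ChromosomeName(c),), (b1, b2, b3))
    if kind is EventKind.DERIVATIVE:
        c1, c2 = rng.sample(chroms, 2)
        t = Event(
            EventKind.TRANSLOCATION,
            Level.BAND,
            (ChromosomeName(c1), ChromosomeName(c2)),
            (_sample_band(rng, band_map, c1), _sample_band(rng, band_map, c2)),
        )
        return Event(
            EventKind.DERIVATIVE,
            Level.BAND,
            (ChromosomeName(c1), ChromosomeName(c2)),
            (t.breakpoints[0],),
            constituents=(t,),
        )
    c = rng.choice(chroms)
    if kind in (
        EventKind.DUPLICATION,
        EventKind.INVERSION,
        EventKind.QUADRUPLICATION,
        EventKind.RING,
        EventKind.TRIPLICATION,
    ):
        b1, b2 = _sample_interval(rng, band_map, c)
        return Event(kind, Level.BAND, (ChromosomeName(c),), (b1, b2))
    if kind is EventKind.DELETION:
        # terminal (one breakpoint) or interstitial (two) deletion
        if rng.random() < 0.5:
            return Event(kind, Level.BAND, (ChromosomeName(c),), (_sample_band(rng, band_map, c),))
        b1, b2 = _sample_interval(rng, band_map, c)
        return Event(kind, Level.BAND, (ChromosomeName(c),), (b1, b2))
    return Event(kind, Level.BAND, (ChromosomeName(c),), (_sample_band(rng, band_map, c),))


def _numerical_event(rng: random.Random, k_so_far: Karyotype) -> Event | None:
    gain = rng.random() < 0.5
    # a loss must leave a non-negative copy number and at least one sex chromosome
    candidates = []
    for c in CHROMOSOME_LABELS:
        cn = copy_number(k_so_far, c)
        if gain:
            candidates.append(c)
        elif cn >= 1:
            if c in ("X", "Y"):
                sex_left = copy_number(k_so_far, "X") + copy_number(k_so_far, "Y")
                if sex_left <= 1:
                    continue
            candidates.append(c)
    if not candidates:
        return None
    c = rng.choice(candidates)
    kind = EventKind.ADDITION if gain else EventKind.DELETION
    return Event(kind, Level.CHROMOSOME, (ChromosomeName(c),), delta=+1 if gain else -1)


def generate(config: GeneratorConfig, band_map: BandMap) -> list[Karyotype]:
    """Generate ``config.n`` valid karyotypes, deterministically in the seed."""
    from .parser import _event_sort_key, _merge_duplicates

    rng = random.Random(config.seed)
    kinds = [k for k, w in config.event_kind_weights.items() if w > 0]
    weights = [config.event_kind_weights[k] for k in kinds]
    out: list[Karyotype] = []
    while len(out) < config.n:
        base = BaseKaryotype(2, rng.choice(["XX", "XY"]))
        n_events = rng.randint(0, config.max_events_per_karyotype)
        events: list[Event] = []
        for _ in range(n_events):
            if rng.random() < config.numerical_event_probability:
                e = _numerical_event(rng, Karyotype(base, tuple(events)))
                if e is not None:
                    events.append(e)
            else:
                events.append(_structural_event(rng, rng.choices(kinds, weights)[0], band_map))
        # store in canonical emission order so parse(canonical(k)) == k
        merged = tuple(sorted(_merge_duplicates(events), key=_event_sort_key))
        k = Karyotype(base, merged).with_declared_total(
            chromosome_count(Karyotype(base, merged))
        )
        # rare event mixes can drive a copy number negative; draw again
        if validate(k, band_map):
            continue
        out.append(k)
    return out


def write_iscn(karyotypes: list[Karyotype], sink: IO[str]) -> int:
    """Write one canonical designation per line; returns the line count."""
    from .parser import canonical_iscn

    n = 0
    for k in karyotypes:
        sink.write(canonical_iscn(k) + "\n")
        n += 1
    return n
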