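"""Four interchangeable representations of band order.

Band order is what turns a two-breakpoint event into a set of affected bands
(a deletion from 1p31 to 1p21 also hits 1p22).  Order can be represented in
several ways with different costs; the four backends here answer the same
interval query through different data structures, except *no_order*, which
records existence only and refuses interval queries:

- ``no_order``        : band existence only; no interval capability
- ``enumeration``     : every band pair's inclusive interval precomputed
- ``sequence_pattern``: next/rest links, answered by traversal
- ``data_property``   : integer positions, answered by comparison
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass
from typing import Callable

from .band_map import BandLabel, BandMap, DomainError
from .model import Karyotype, Level, affected_bands

BACKEND_NAMES = ("no_order", "enumeration", "sequence_pattern", "data_property")


class CapabilityError(RuntimeError):
    """The backend does not support interval queries."""


class UnknownBackendError(KeyError):
    pass


@dataclass
class OrderBackend:
    name: str
    supports_between: bool
    _between: Callable[[BandLabel, BandLabel], list[BandLabel]] | None = None
    _exists: Callable[[str], bool] | None = None

    def band_exists(self, label: str) -> bool:
        return self._exists(label)

    def bands_between(self, x: BandLabel | str, y: BandLabel | str) -> list[BandLabel]:
        if not self.supports_between:
            raise CapabilityError(f"backend {self.name!r} does not represent order")
        if isinstance(x, str):
            x = BandLabel.parse(x)
        if isinstance(y, str):
            y = BandLabel.parse(y)
        return self._between(x, y)


def _fine_sequences(band_map: BandMap) -> dict[str, list[BandLabel]]:
    return {c.label: band_map.traversal(c) for c in band_map.chromosomes}


def _resolve(band_map: BandMap, seq_pos: dict[str, int], lbl: BandLabel, last: bool) -> int:
    """Position of a band in the fine traversal, expanding parent bands."""
    key = str(lbl)
    if key in seq_pos:
        return seq_pos[key]
    desc = [seq_pos[str(d)] for d in band_map.sub_bands(lbl) if str(d) in seq_pos]
    if not desc:
        raise DomainError(f"band {lbl} not placeable in order")
    return max(desc) if last else min(desc)


def build_backend(band_map: BandMap, name: str) -> OrderBackend:
    """Construct one of the four order representations over a band map."""
    if name not in BACKEND_NAMES:
        raise UnknownBackendError(name)
    exists = band_map.band_exists

    if name == "no_order":
        return OrderBackend(name, supports_between=False, _exists=exists)

    sequences = _fine_sequences(band_map)

    if name == "enumeration":
        # every same-chromosome pair's interval, explicitly stated
        table: dict[tuple[str, str], tuple[BandLabel, ...]] = {}
        for chrom, seq in sequences.items():
            for i in range(len(seq)):
                for j in range(i, len(seq)):
                    interval = tuple(seq[i : j + 1])
                    table[(str(seq[i]), str(seq[j]))] = interval
                    table[(str(seq[j]), str(seq[i]))] = interval
            # parent bands map onto their descendant span
            for e in band_map.bands_of(chrom):
                if str(e.label) not in {str(s) for s in seq}:
                    pos = {str(s): i for i, s in enumerate(seq)}
                    lo = _resolve(band_map, pos, e.label, last=False)
                    hi = _resolve(band_map, pos, e.label, last=True)
                    for other_i, other in enumerate(seq):
                        span = tuple(seq[min(lo, other_i) : max(hi, other_i) + 1])
                        table[(str(e.label), str(other))] = span
                        table[(str(other), str(e.label))] = span

        def between_enum(x: BandLabel, y: BandLabel) -> list[BandLabel]:
            if x.chromosome != y.chromosome:
                raise DomainError("bands on different chromosomes")
            try:
                return list(table[(str(x), str(y))])
            except KeyError:
                raise DomainError(f"no interval recorded for ({x}, {y})") from None

        return OrderBackend(name, True, between_enum, exists)

    if name == "sequence_pattern":
        # 'next' links from each band to its successor; answer by walking
        nxt: dict[str, BandLabel] = {}
        heads: dict[str, BandLabel] = {}
        for chrom, seq in sequences.items():
            if seq:
                heads[chrom] = seq[0]
            for a, b in zip(seq, seq[1:]):
                nxt[str(a)] = b

        def between_seq(x: BandLabel, y: BandLabel) -> list[BandLabel]:
            if x.chromosome != y.chromosome:
                raise DomainError("bands on different chromosomes")
            seq = sequences[x.chromosome.label]
            pos = {str(s): i for i, s in enumerate(seq)}
            lo_i = _resolve(band_map, pos, x, last=False)
            hi_i = _resolve(band_map, pos, y, last=True)
            if lo_i > hi_i:
                lo_i = _resolve(band_map, pos, y, last=False)
                hi_i = _resolve(band_map, pos, x, last=True)
            start, stop = seq[lo_i], seq[hi_i]
            out = [start]
            cur = start
            while cur != stop:
                cur = nxt[str(cur)]
                out.append(cur)
            return out

        return OrderBackend(name, True, between_seq, exists)

    # data_property: strictly increasing integers pter->qter, compare to answer
    value: dict[str, int] = {}
    by_chrom_values: dict[str, list[tuple[int, BandLabel]]] = {}
    for chrom, seq in sequences.items():
        pairs = [(i, lbl) for i, lbl in enumerate(seq)]
        by_chrom_values[chrom] = pairs
        for i, lbl in pairs:
            value[str(lbl)] = i

    def between_data(x: BandLabel, y: BandLabel) -> list[BandLabel]:
        if x.chromosome != y.chromosome:
            raise DomainError("bands on different chromosomes")
        seq = sequences[x.chromosome.label]
        pos = {str(s): i for i, s in enumerate(seq)}
        vx_lo = _resolve(band_map, pos, x, last=False)
        vx_hi = _resolve(band_map, pos, x, last=True)
        vy_lo = _resolve(band_map, pos, y, last=False)
        vy_hi = _resolve(band_map, pos, y, last=True)
        lo, hi = min(vx_lo, vy_lo), max(vx_hi, vy_hi)
        return [lbl for v, lbl in by_chrom_values[x.chromosome.label] if lo <= v <= hi]

    return OrderBackend(name, True, between_data, exists)


def build_all(band_map: BandMap) -> dict[str, OrderBackend]:
    return {n: build_backend(band_map, n) for n in BACKEND_NAMES}


# -- benchmarking -----------------------------------------------------------

@dataclass
class BenchmarkRow:
    backend: str
    n: int
    seconds: float
    classifications_checksum: str
    unsupported: int  # interval queries the backend could not answer


def _classify_via_backend(
    k: Karyotype, band_map: BandMap, backend: OrderBackend
) -> tuple[tuple[str, ...], int]:
    """Class names plus affected-band sets, interval queries routed through
    *backend*; returns (record, n_unsupported)."""
    from .classification import classify

    names = sorted(classify(k))
    record = list(names)
    unsupported = 0
    for e in k.events:
        if e.level is not Level.BAND:
            continue
        try:
            if backend.supports_between:
                # recompute via the backend's own interval machinery
                bands = _affected_via(e, band_map, backend)
            else:
                raise CapabilityError(backend.name)
            record.append(",".join(sorted(str(b) for b in bands)))
        except CapabilityError:
            unsupported += 1
            record.append("<unsupported>")
    return tuple(record), unsupported


def _affected_via(e, band_map: BandMap, backend: OrderBackend) -> set[BandLabel]:
    from .model import INTERVAL_KINDS, EventKind

    bps = e.breakpoints
    if e.kind in INTERVAL_KINDS and len(bps) == 2 and bps[0].chromosome == bps[1].chromosome:
        return set(backend.bands_between(bps[0], bps[1]))
    if e.kind is EventKind.DELETION and len(bps) == 1:
        tel = band_map.terminal_band(bps[0].chromosome, bps[0].arm)
        return set(backend.bands_between(bps[0], tel))
    return affected_bands(e, band_map)


def benchmark_backends(
    n_list: list[int],
    seed: int,
    band_map: BandMap | None = None,
    backends: list[str] | None = None,
) -> list[BenchmarkRow]:
    """Classify n generated karyotypes through each backend and time it.

    Correctness comes first: for every n, all interval-capable backends must
    produce identical classification records before any timing is reported.
    """
    from .band_map import default_band_map
    from .generator import GeneratorConfig, generate

    bm = band_map if band_map is not None else default_band_map()
    names = backends if backends is not None else list(BACKEND_NAMES)
    if sorted(n_list) != list(n_list):
        raise ValueError("n_list must be ascending")

    rows: list[BenchmarkRow] = []
    for n in n_list:
        karyotypes = generate(GeneratorConfig(seed=seed, n=n), bm)
        checksums: dict[str, str] = {}
        for name in names:
            backend = build_backend(bm, name)
            t0 = time.perf_counter()
            records = []
            unsupported = 0
            for k in karyotypes:
                rec, miss = _classify_via_backend(k, bm, backend)
                records.append(rec)
                unsupported += miss
            elapsed = time.perf_counter() - t0
            digest = hashlib.sha256(repr(sorted(records)).encode()).hexdigest()[:16]
            checksums[name] = digest
            rows.append(BenchmarkRow(name, n, elapsed, digest, unsupported))
        capable = [c for b, c in checksums.items() if b != "no_order"]
        if len(set(capable)) > 1:
            raise AssertionError(
                f"backends disagree at n={n}: "
                + ", ".join(f"{b}={c}" for b, c in checksums.items())
            )
    return rows
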