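"""Defined karyotype classes and subsumption as decision procedures.

Each defined class pairs a name with a membership predicate over karyotypes
and a position in a parent lattice (member of a child implies member of every
ancestor).  Sex is the one deliberately three-valued question: a karyotype is
male iff it derives from a 46,XY-type base, female iff from 46,XX — so
45,X,-Y is male (it lost its Y) while Turner's 45,X, derived from 46,XN,
is neither, because which chromosome was lost is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .band_map import BandMap, default_band_map
from .model import BaseKaryotype, Event, EventKind, Karyotype, Level, validate


class UnregisteredNameError(KeyError):
    """Neither a defined class nor a named karyotype of that name."""


@dataclass(frozen=True)
class DefinedClass:
    name: str
    predicate: Callable[[Karyotype], bool]
    parents: frozenset[str] = frozenset()

    def __contains__(self, k: Karyotype) -> bool:
        return self.predicate(k)


@dataclass(frozen=True)
class NamedKaryotype:
    name: str
    definition: Karyotype


def sex_of(k: Karyotype) -> str:
    """'male' | 'female' | 'undetermined', from the base the karyotype derives from."""
    comp = k.base.sex_complement
    if "N" in comp:
        return "undetermined"
    return "male" if "Y" in comp else "female"


def _is_numerical(e: Event) -> bool:
    return e.level is Level.CHROMOSOME and e.kind in (EventKind.ADDITION, EventKind.DELETION)


def _numerical_delta_on(k: Karyotype, want_autosome: bool, sign: int) -> bool:
    """Any whole-chromosome gain (sign>0) or loss (sign<0) of an (allo/auto)some.

    Tested through copy-number deltas so that spelling variants agree.
    """
    for e in k.events:
        if not _is_numerical(e) or not e.chromosomes:
            continue
        c = e.chromosomes[0]
        if c.is_autosome == want_autosome and (e.delta > 0) == (sign > 0):
            return True
    return False


#: Table-style structural kinds that can appear at band level
_BAND_LEVEL_KINDS = [k for k in EventKind if k is not EventKind.MARKER]


def _make_registry() -> dict[str, DefinedClass]:
    reg: dict[str, DefinedClass] = {}

    def add(name: str, predicate: Callable[[Karyotype], bool], *parents: str) -> None:
        reg[name] = DefinedClass(name, predicate, frozenset(parents))

    for ploidy, name in ((1, "Haploid"), (2, "Diploid"), (3, "Triploid"), (4, "Tetraploid")):
        add(name, lambda k, p=ploidy: k.base.ploidy == p)

    add("Male", lambda k: sex_of(k) == "male")
    add("Female", lambda k: sex_of(k) == "female")

    add("NumericalAbnormal", lambda k: any(_is_numerical(e) for e in k.events))
    add(
        "NumericalAbnormalAutosomalGain",
        lambda k: _numerical_delta_on(k, True, +1),
        "NumericalAbnormal",
    )
    add(
        "NumericalAbnormalAutosomalLoss",
        lambda k: _numerical_delta_on(k, True, -1),
        "NumericalAbnormal",
    )
    add(
        "NumericalAbnormalAllosomalGain",
        lambda k: _numerical_delta_on(k, False, +1),
        "NumericalAbnormal",
    )
    add(
        "NumericalAbnormalAllosomalLoss",
        lambda k: _numerical_delta_on(k, False, -1),
        "NumericalAbnormal",
    )

    add("StructuralAbnormal", lambda k: any(e.level is Level.BAND for e in k.events))
    for kind in _BAND_LEVEL_KINDS:
        add(
            f"StructuralAbnormal{kind.display_name.replace(' ', '')}",
            lambda k, kd=kind: any(
                e.level is Level.BAND and e.kind is kd for e in k.events
            ),
            "StructuralAbnormal",
        )
    return reg


_REGISTRY = _make_registry()


def registry() -> list[DefinedClass]:
    """All defined classes (ploidy, sex, numerical and structural families)."""
    return list(_REGISTRY.values())


def get_class(name: str) -> DefinedClass:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnregisteredNameError(name) from None


def is_member(k: Karyotype, c: DefinedClass | str) -> bool:
    if isinstance(c, str):
        c = get_class(c)
    return c.predicate(k)


def classify(k: Karyotype) -> set[str]:
    """Names of every defined class the karyotype belongs to (ancestor-closed)."""
    names = {c.name for c in _REGISTRY.values() if c.predicate(k)}
    changed = True
    while changed:  # close under parent edges (defensive; predicates already imply it)
        changed = False
        for n in list(names):
            for p in _REGISTRY[n].parents:
                if p not in names:
                    names.add(p)
                    changed = True
    return names


# -- named karyotypes -------------------------------------------------------

def _named_karyotypes(band_map: BandMap) -> dict[str, NamedKaryotype]:
    from .parser import parse

    defs = {
        # congenital syndromes derive from 46,XN unless sex is fixed:
        "DownSyndrome": parse("47,XN,+21", band_map),
        "PraderWilliSyndrome": parse("46,XN,del(15)(q11q12)", band_map),
        # Turner: one sex chromosome lost, which one unknowable -> base 46,XN
        "TurnerSyndrome": parse("45,X", band_map),
        "k46_XX": Karyotype(BaseKaryotype(2, "XX")),
        "k46_XY": Karyotype(BaseKaryotype(2, "XY")),
        "k46_XN": Karyotype(BaseKaryotype(2, "XN")),
    }
    return {name: NamedKaryotype(name, k) for name, k in defs.items()}


_NAMED: dict[str, NamedKaryotype] | None = None


def named_karyotypes(band_map: BandMap | None = None) -> dict[str, NamedKaryotype]:
    global _NAMED
    if _NAMED is None:
        bm = band_map if band_map is not None else default_band_map()
        named = _named_karyotypes(bm)
        for nk in named.values():
            findings = validate(nk.definition, bm)
            assert not findings, f"named karyotype {nk.name} invalid: {findings}"
        _NAMED = named
    return _NAMED


def is_superclass(sub: str | NamedKaryotype | DefinedClass, sup: str | DefinedClass) -> bool:
    """Does *sup* subsume *sub*?

    A named karyotype is subsumed by a class iff its definition is a member;
    a defined class is subsumed iff *sup* is reachable through parent edges.
    """
    sup_cls = get_class(sup) if isinstance(sup, str) else sup
    if isinstance(sub, str):
        named = named_karyotypes()
        if sub in named:
            sub = named[sub]
        elif sub in _REGISTRY:
            sub = _REGISTRY[sub]
        else:
            raise UnregisteredNameError(sub)
    if isinstance(sub, NamedKaryotype):
        return is_member(sub.definition, sup_cls)
    # lattice reachability
    frontier = [sub.name]
    seen = set()
    while frontier:
        n = frontier.pop()
        if n == sup_cls.name:
            return True
        if n in seen:
            continue
        seen.add(n)
        frontier.extend(_REGISTRY[n].parents)
    return False
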