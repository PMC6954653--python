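# Methods

## The model

A karyotype is a base complement plus an ordered list of change events, the
reading ISCN itself uses: the events are interpretative — the changes that
*could have* produced the observed complement, like an edit script, not a
history. Bases are `k{23·ploidy}_{complement}` for ploidy 1–4 with a sex
complement over {X, Y, N}; N is an unknown sex chromosome, used when the
derivation cannot name what was gained or lost (`45,X` derives from 46,XN).

Events carry a kind (19 closed abbreviations), a level (whole-chromosome or
band), 1–3 target chromosomes, 0–3 band breakpoints, and a multiplicity
(repeated identical fields accumulate). Derivative chromosomes (`der`) are
containers: their trailing specification is parsed into constituent events;
the container itself contributes no count change.

### Count accounting

`chromosome_count = 23·ploidy + Σ δ(e)`. The deltas: `+c` → +1, `-c` → −1
(×multiplicity); `fis` +1 (one chromosome becomes two); `dic`/`tas` −1 and
`trc` −2 (two/three chromosomes fuse into one); `mar` +1 per marker; every
other structural kind 0. The fusion/fission/marker deltas are ISCN practice
rather than something the formal model dictates; they are the convention a
cytogeneticist applies when balancing a designation's total.

Per-chromosome copy number assigns each event's delta to named chromosomes:
fusions debit the first-listed chromosome(s), fissions credit their
chromosome. Markers have no chromosome identity, so the conservation law is
`Σ_c copy_number(c) + markers = chromosome_count`; for marker-free
karyotypes (all generator output) the marker term vanishes.

### Base inference

Parsing must recover which base a designation derives from. Explicit sex
events are undone (`45,X,-Y`: observed X + returned Y → base XY). Each
*implicit* sex event also moves the total by one, so ploidy solves
`22·p = declared_total − explicit_deltas − |observed complement|` uniquely.
A shortfall no event explains pads the base with N and adds an implicit loss
of an unknown sex chromosome (`45,X` → 46,XN base, one loss — hence
undetermined sex). A surplus (e.g. `47,XXY`) removes a *duplicated* letter,
so the base keeps one of each observed kind: `47,XXY` derives from 46,XY and
classifies male, matching clinical reading of Klinefelter; the alternative
(deriving such surpluses from XN) was rejected because the observed
complement pins the base down up to which copy is extra, and the duplicate
is the only candidate for the gain.

## The band map

All 24 chromosome types with p/q arms, ~325 bands at the conventional
low-resolution (undotted) level, plus the 17q21 dotted sub-bands
(17q21.1–17q21.33) to exercise resolution handling. Band inventories are
conventional idiogram lists; the package treats the table as data (any
fuller 850-band table in the same TSV dialect can be dropped in) and its
tests rely on internal consistency — ordering, parenthood, arm structure —
not on any particular inventory.

Numerical choices:

- **Linearization.** pter→qter: p-arm designations descending, q-arm
  ascending — forced by ISCN's numbering away from the centromere.
- **Resolution is cumulative.** A band visible at level L stays visible at
  all finer levels; finer levels additionally reveal sub-bands. The
  traversal at resolution r replaces a band by its sub-bands where those are
  visible, giving a partition of the chromosome at every r.
- **Interval queries** default to the finest level (850). An endpoint that
  is a parent band at the query resolution expands to its outermost visible
  descendant, keeping intervals inclusive. Intervals are symmetric in their
  endpoints and may span the centromere.
- **The centromere is a boundary**, not a band: the junction between the
  p11-most and q11-most bands. Breakpoints are always bands.

## Classification

Defined classes are plain predicates with parent edges (30 classes: four
ploidies, Male/Female, NumericalAbnormal with four gain/loss children split
by autosome/allosome, StructuralAbnormal with one child per band-capable
event kind). Subsumption needs no reasoner: a named karyotype is subsumed by
a class iff its definition satisfies the predicate; class-to-class
subsumption is reachability over parent edges. Closed-world booleans are
used everywhere except sex, which is three-valued (male/female/undetermined)
because derivation from 46,XN deliberately leaves the question open — the
one place open-world semantics is load-bearing.

Named karyotypes ship with XN bases unless the condition fixes sex:
Down = 47,XN,+21, Prader–Willi = 46,XN,del(15)(q11q12), Turner = 45,X
(46,XN base). Gain/loss classes test copy-number deltas, not event spelling.

## The generator

Emulates a stream of single-clone karyotype designations: diploid XX/XY
bases, 0–3 events each, a 0.3 chance per slot of a numerical event
(gain/loss of a uniformly chosen chromosome, guarded so no copy number goes
negative and at least one sex chromosome remains), otherwise a structural
kind drawn uniformly over the 18 band-capable kinds with breakpoints sampled
from the map. Defaults are visible on `GeneratorConfig`. Output is
deterministic per seed, validates cleanly, and round-trips through the
parser (events are stored in canonical emission order to make round-trip
equality exact).

What it does *not* emulate: real aberration spectra (tumour-type
frequencies, recurrent translocations), mosaic/composite clones, uncertain
breakpoints. Passing property tests on this stream therefore demonstrates
the machinery's correctness on well-formed single-clone designations, not
robustness to the messier dialects of clinical databases.

## Order backends and the scaling run

Four representations of band order sit behind one interface; `enumeration`
is the oracle (all intervals explicitly stated) and the others are checked
against it exhaustively over every same-chromosome band pair. The benchmark
classifies n ∈ {10, 100, 1000, 10000} generated karyotypes per backend,
resolving each structural event's affected bands through that backend,
asserts identical classification checksums across the interval-capable
backends first, and only then reports wall times — timings are
hardware-bound and never asserted. At these problem sizes the full run takes
a few seconds on one CPU.

## Supported ISCN dialect

Single-clone designations: total, sex field over {X,Y,N}, then events; all
19 event kinds in one/two-chromosome, one-to-three-breakpoint forms;
whitespace insignificant. Mosaic clones (`/`), `idem`, uncertainty (`?`) and
approximate totals (`45~48`) are rejected with an explicit
unsupported-dialect error — full ISCN is informal enough that silent guesses
would be worse than refusal.

## Known limitations

- No base-pair coordinates, stain intensity or heteromorphic variants; the
  band table is positional only.
- Declared totals are authoritative for validation; computed totals for
  classification.
- `47,XXY`-style surpluses rely on the duplicated-letter rule above; exotic
  complements (e.g. multiple distinct unexplained gains) fall back to the
  same rule letter by letter.
- The packaged band table is the ~400-band conventional inventory, not the
  full 850-band reference table; with a fuller table loaded the band count
  grows past 800 but no behaviour changes.
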