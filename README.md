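# karyokit

Computable human karyotypes: parse ISCN designations, validate them against a
chromosome-band map, classify them with defined karyotype classes, and compare
representations of band order.

Clinical cytogenetics records a person's (or tumour's) chromosome complement
as an ISCN string such as `46,XY,del(15)(q11q12)` — a base complement plus a
list of interpretative change events. These strings are compact and
expressive, but they are informally specified: hard to validate, hard to
search, hard to compute with. `karyokit` gives them a formal, event-based
model:

- a **karyotype** is a base complement *B* (46,XX / 46,XY / 46,XN and their
  haploid/triploid/tetraploid analogues, so |B| = 23·ploidy) together with an
  ordered list of events *e₁…eₙ* (whole-chromosome gains/losses `±c` and the
  structural event kinds `add, del, der, dic, dup, fis, fra, hsr, ins, inv,
  i, mar, neo, qdp, r, tas, t, trc, trp`, each with target chromosomes and
  band breakpoints);
- the chromosome total is `|B| + Σ δ(eᵢ)` and per-chromosome copy number is
  the base's contribution plus the events' gains and losses;
- **sex is derivational**: a karyotype is male iff it derives from 46,XY,
  female iff from 46,XX — so `45,X,-Y` is male even though it has no Y, and
  Turner's `45,X` (derived from 46,XN, the lost chromosome unknown) is
  neither male nor female;
- bands live in an ordered **partonomy** (band ⊂ arm ⊂ chromosome) with
  resolution levels (300–850 bands), so a deletion `del(1)(p31p21)` is known
  to affect exactly {1p31, 1p22, 1p21};
- **defined classes** (Diploid, Male, NumericalAbnormal,
  StructuralAbnormalDeletion, …) are membership predicates arranged in a
  subsumption lattice and usable as queries.

It is intended for cytogeneticists, clinical-database maintainers and
bioinformaticians who need karyotype strings to be checkable and searchable
rather than opaque text.

## Worked example

```python
from karyokit import (classify, chromosome_count, copy_number,
                      default_band_map, parse, sex_of)

band_map = default_band_map()
k = parse("45, X,-Y", band_map)          # whitespace is insignificant
print(chromosome_count(k))               # 45
print(copy_number(k, "Y"), copy_number(k, "X"))   # 0 1
print(sex_of(k))                         # male
print(sorted(classify(k)))
# ['Diploid', 'Male', 'NumericalAbnormal', 'NumericalAbnormalAllosomalLoss']

print([str(b) for b in band_map.bands_between("1p31", "1p21")])
# ['1p31', '1p22', '1p21']
```

The karyotype lost one Y from a 46,XY base: 45 chromosomes, zero copies of Y,
yet male — sex follows the derivation, not the chromosomes present. The band
interval shows why order matters: a deletion spanning 1p31→1p21 also removes
sequence in 1p22, and in only that band.

The same functionality is available from the shell:

```sh
echo "45,X,-Y" | karyokit classify
# {"input": "45,X,-Y", "classes": ["Diploid", "Male", "NumericalAbnormal",
#   "NumericalAbnormalAllosomalLoss"], "sex": "male"}
karyokit test-fixtures        # run the packaged karyotype-vs-class table
karyokit benchmark --sizes 10,100,1000,10000 --seed 7   # band-order backends
```

The `examples/` directory holds short narrative scripts, one per capability:
parsing and classification, band-interval queries, seeded generation with
parser round-trips, and the band-order backend comparison.

## Band order backends

Band order can be represented four ways behind one interface: `no_order`
(existence only — interval queries are refused, not guessed), `enumeration`
(every pair's interval precomputed), `sequence_pattern` (next-links walked at
query time) and `data_property` (integer positions compared at query time).
`karyokit benchmark` classifies seeded random karyotypes through each backend,
asserts the interval-capable backends agree exactly (checksums), and reports —
never asserts — the timings.

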