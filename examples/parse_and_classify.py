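"""Parse ISCN designations and classify them against the defined classes.

Each designation is read as a base complement plus change events; the
classifier then answers queries such as "is this numerically abnormal?"
and the derivation-based sex question (45,X,-Y is male because it derives
from 46,XY; Turner's 45,X derives from 46,XN and stays undetermined).
"""

from karyokit import (
    canonical_iscn,
    chromosome_count,
    classify,
    copy_number,
    default_band_map,
    parse,
    sex_of,
)

band_map = default_band_map()

for iscn in ["46,XY", "45, X,-Y", "47,XX,+21", "46,XY,del(15)(q11q12)", "45,X"]:
    k = parse(iscn, band_map)
    print(f"{iscn!r:28} -> {canonical_iscn(k):24}"
          f" base={k.base.name} total={chromosome_count(k)}"
          f" sex={sex_of(k)}")
    print(f"{'':28}    classes: {', '.join(sorted(classify(k))) or '(none)'}")

k = parse("45,X,-Y", band_map)
print("\ncopy numbers for 45,X,-Y:  X =", copy_number(k, "X"), " Y =", copy_number(k, "Y"))
print("-> one X, no Y, yet classified male: sex follows the 46,XY derivation,")
print("   not the chromosomes present.")
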