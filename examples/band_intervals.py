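"""Band partonomy queries: existence, order, intervals and resolution.

A deletion between two breakpoints affects every band in between — the
band map knows the pter->qter order, so the interval from 1p31 to 1p21
contains exactly 1p22 besides its endpoints.
"""

from karyokit import default_band_map
from karyokit.model import affected_bands
from karyokit.parser import parse_event

band_map = default_band_map()

print("1p35 exists:", band_map.band_exists("1p35"))
print("1p99 exists:", band_map.band_exists("1p99"))

between = band_map.bands_between("1p31", "1p21")
print("bands from 1p31 to 1p21:", [str(b) for b in between])
print("-> a deletion del(1)(p31p21) also removes sequence in 1p22.")

e = parse_event("del(1)(p31p21)", band_map)
print("affected_bands:", sorted(str(b) for b in affected_bands(e, band_map)))

print("\n17q21 sub-bands (visible from the 550-band level):",
      [str(b) for b in band_map.sub_bands("17q21")])
print("17q21.31 visible at 300 bands:", band_map.seen_at_resolution("17q21.31", 300))
print("17q21.31 visible at 850 bands:", band_map.seen_at_resolution("17q21.31", 850))

print("\ninterval spanning the centromere, 3p21 to 3q21:",
      [str(b) for b in band_map.bands_between("3p21", "3q21")])
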