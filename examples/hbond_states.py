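"""Hydrogen-bond taxonomy of non-canonical pairs.

Runs the duplex-constrained placement search for the maximum number of
simultaneous hydrogen bonds each pair type can form in anti/anti
orientation, then builds example pair geometries at every achievable bond
count and classifies them back (the confusion-matrix identity).
"""

from helixbend import (
    MismatchGeometrySpec,
    build_mismatch_pair,
    classify_pair_state,
    max_simultaneous_hbonds,
)

print("pair  max simultaneous H-bonds (anti/anti, duplex-embedded)")
for pair in ("GC", "AU", "GU", "UU", "CC", "CU", "AA"):
    print(f" {pair}    {max_simultaneous_hbonds(pair)}")

print("\nbuild -> classify round trip over all achievable states:")
for pair in ("UU", "CC", "CU", "AA"):
    for k in range(max_simultaneous_hbonds(pair) + 1):
        c = build_mismatch_pair(MismatchGeometrySpec(pair, k))
        state = classify_pair_state(c, (1, 1))
        print(f" {pair} built with {k} bond(s) -> classified {state.count}")
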