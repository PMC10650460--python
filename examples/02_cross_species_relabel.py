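"""Cross-species isoform relation between two canonical matures.

Two species carry the same miRNA but deposit canonical matures differing by
one 3' base. Decomposing each species' canonical against the other's
reference expresses the relation: the shorter one is the longer species'
"Trim" isoform, and the longer one is the shorter species' non-templated
"Plus" isoform (when the extra base is absent from the hairpin at that
position).
"""

from isomirkit import HairpinRef, MatureAnnotation, relabel_against

mature_long = "UCCCUGAGACCCUAACUUGUGA"   # 22 nt, ends ...UGA
mature_short = mature_long[:-1]          # 21 nt, the same minus terminal A

# species L: hairpin carries the long mature; next base is G (A non-templated)
hairpin_l = HairpinRef("spl-mir-x", "CGUA" + mature_long + "GCUAG")
annot_l = MatureAnnotation("spl-miR-x-5p", "spl-mir-x", 4, 26)

# species S: hairpin carries the short mature; next base is C
hairpin_s = HairpinRef("sps-mir-x", "CGUA" + mature_short + "CCUAG")
annot_s = MatureAnnotation("sps-miR-x-5p", "sps-mir-x", 4, 25)

short_vs_long = relabel_against(mature_short, hairpin_l, annot_l)
long_vs_short = relabel_against(mature_long, hairpin_s, annot_s)

print(f"species-S canonical against species-L reference: {short_vs_long.label}")
print(f"species-L canonical against species-S reference: {long_vs_short.label}")
print(f"self-relabel is canonical: {relabel_against(mature_long, hairpin_l, annot_l).label}")

# Expected: 'Trim A' and 'Plus A' — the two canonicals are each other's
# one-base 3' isoforms, with the addition non-templated on the short hairpin.
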