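"""Parse cytological band notation and do interval algebra on it.

Duplication extents are written in polytene map coordinates ("2C1-3E4");
the map gives a total order on bands but no physical scale, so overlap and
intersection are ordinal operations.
"""

from dmimap import band_leq, intersect, overlaps, parse_band, parse_interval

a = parse_interval("12C1-12F4")  # Dp(1;Y)BSC186
b = parse_interval("12E9-13C5")  # Dp(1;Y)BSC269
c = parse_interval("11C2-11D1")  # Dp(1;Y)BSC126

print(f"{a} overlaps {b}: {overlaps(a, b)}")
print(f"shared region: {intersect(a, b)}")
print(f"{a} overlaps {c}: {overlaps(a, c)}")

partial = parse_interval("9C-10B")  # endpoints completed outward
print(f"'9C-10B' expands to {partial} (right end = last band of 10B)")

h = parse_band("h28")
print(f"heterochromatin block {h} lies distal to 20F3:", end=" ")
print(band_leq(parse_band("20F3"), h))

# If two lethal duplications overlap, the conservative assumption is a single
# shared lethal allele in the intersection; disjoint duplications must carry
# distinct alleles.
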