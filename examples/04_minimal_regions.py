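"""Reduce overlapping lethal duplications to minimal distinct regions.

Overlap means a possibly shared cause, so the minimal explanation is the
smallest set of bands ("piercing bands") hitting every lethal interval —
solved exactly by the right-endpoint greedy.  The count is conservative: it
can only underestimate the number of distinct lethal alleles.
"""

from dmimap import minimal_regions, parse_interval

lethal = [
    ("BSC126", parse_interval("11C2-11D1")),
    ("BSC327", parse_interval("11D5-11E8")),
    ("BSC186", parse_interval("12C1-12F4")),
    ("BSC269", parse_interval("12E9-13C5")),
]

regions = minimal_regions(lethal, stage="embryonic")
print(f"{len(lethal)} lethal duplications -> {len(regions)} distinct regions\n")
for i, r in enumerate(regions, 1):
    print(f"region {i}: core {r.core}, pierced at {r.piercing_band}, "
          f"members {', '.join(r.members)}")

# The two division-11 duplications are disjoint (two separate regions); the
# two division-12 duplications overlap in 12E9-12F4 and merge into one.
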