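"""Single- vs paired-end duplicate marking on a repetitive centromere.

Centromeric repeat arrays collapse many true fragments onto shared read-1
coordinates.  With single-end information those fragments look like PCR
duplicates and are discarded; the mate coordinate disambiguates them.  This
script counts how many centromeric G1 fragments survive marking in each mode.
"""

import numpy as np

from centrotime import build_toy_genome, simulate_reads, simulate_rt_truth
from centrotime.reads import mark_duplicates, read1_position

layout = build_toy_genome()
truth = simulate_rt_truth(layout, seed=1)
reads = simulate_reads(layout, truth, "G1", n_fragments=400_000, seed=31)

r1 = read1_position(reads)
cs, ce = layout.centromere("chr1")
in_cen = (reads["chrom"].to_numpy() == "chr1") & (r1 >= cs) & (r1 < ce)
print(f"centromeric fragments (chr1): {in_cen.sum()}")

for mode in ("single", "paired"):
    marked = mark_duplicates(reads, mode)
    kept = int((~marked["is_dup"].to_numpy() & in_cen).sum())
    print(f"  retained after {mode:>6}-end marking: {kept:6d} "
          f"({kept / in_cen.sum():.1%})")

print("\nPaired-end marking retains the bulk of centromeric fragments because")
print("collapsed read-1 coordinates still differ in their mate coordinate;")
print("single-end marking misreads the repeat structure as duplication.")
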