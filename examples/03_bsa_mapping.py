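"""Map a causal locus by bulked segregant analysis on array calls.

Simulates 200 BC2F1 offspring from inbred parents, splits them into two
bulks by genotype at a hidden causal locus (e.g. a fertility restorer),
takes the majority-consensus genotype of each bulk, and scans the genome
in 1-Mb windows for markers where the bulks differ.  Printed: the peak
window (which should contain the causal position) and the interval
spanned by the nearest differing probes.
"""

import numpy as np
import pandas as pd

from allopanel.applications import (
    bulk_consensus, differential_scan, introgression_report,
)
from allopanel.io import GenomeIndex, Interval
from allopanel.simulate import (
    MarkerMap, cross_dosage, inbred_parents, simulate_cross,
)

L = 10_000_000
mm = MarkerMap({"chr1": L, "chr2": L},
               {"chr1": np.arange(10_001, L, 20_000),
                "chr2": np.arange(10_001, L, 20_000)})
p1, p2 = inbred_parents(mm)
off = simulate_cross(p1, p2, "BC2F1", 200, mm, 2e-6, seed=11)
dos = cross_dosage(off, mm)

causal_i = 180  # marker index on chr1; position of the hidden locus
causal_pos = int(mm.positions["chr1"][causal_i])
carrier = dos[causal_i] > 0
print(f"causal locus at chr1:{causal_pos:,}; "
      f"{int(carrier.sum())} of 200 offspring carry the donor allele")

mids = mm.marker_ids()
codes = np.where(dos == 0, "AA", np.where(dos == 1, "AB", "BB"))
bulk_a = bulk_consensus(pd.DataFrame(codes[:, carrier], index=mids))
bulk_b = bulk_consensus(pd.DataFrame(codes[:, ~carrier], index=mids))

pos = pd.DataFrame({
    "chrom": ["chr1"] * len(mm.positions["chr1"]) + ["chr2"] * len(mm.positions["chr2"]),
    "pos": np.concatenate([mm.positions["chr1"], mm.positions["chr2"]]),
}, index=mids)
scan = differential_scan(bulk_a, bulk_b, pos, GenomeIndex({"chr1": L, "chr2": L}))
chrom, lo, hi = scan.peak
print(f"{scan.total_diff} differing markers; peak 1-Mb window "
      f"{chrom}:{lo:,}-{hi:,} (causal inside: {lo < causal_pos <= hi})")

rep = introgression_report(scan, Interval("chr1", causal_pos - 1, causal_pos))
c, a, b = rep.spanned_interval
print(f"nearest differing probes span {c}:{a:,}-{b:,} "
      f"({(b-a)/1000:.0f} kb candidate interval)")
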