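"""Aggregating per-read calls: site frequencies, binned 6mA tracks, and
IgG background correction.

Run:  python examples/04_aggregate_and_background.py
"""

import pandas as pd

from poremeth.aggregate import (
    background_correct,
    linker_length_distribution,
    methylation_category,
    site_frequencies,
    window_counts,
)

# A toy per-read call table (what `poremeth call` writes).
rows = []
for i in range(8):
    call = "methylated" if i < 6 else "unmethylated"
    rows.append(dict(read_id=f"r{i}", chrom="chr1", start=1000, end=1030,
                     kind="cpg_substring", llr=3.0, call=call, n_hypotheses=2,
                     cpg_positions="1010;1018"))
for i, (start, call) in enumerate([(0, "contains_6mA"), (50, "non_6mA"),
                                   (200, "contains_6mA"), (2600, "contains_6mA")]):
    rows.append(dict(read_id="r0", chrom="chr1", start=start, end=start + 50,
                     kind="adenine_window", llr=12.0, call=call, n_hypotheses=2,
                     cpg_positions=""))
calls = pd.DataFrame(rows)

freq = site_frequencies(calls)
print(freq.to_string(index=False))
for r in freq.itertuples():
    print(f"  site {r.chrom}:{r.start} -> {100 * r.frequency:.0f}% methylated "
          f"({methylation_category(r.frequency)}), coverage {r.coverage}")

counts = window_counts(calls, bin_size=2500)
print("\n6mA-positive windows per 2500-bp bin:")
print(counts.to_string(index=False))

# IgG background correction: 20 positive windows in the antibody track, 4 in
# IgG, at double the IgG coverage -> scaling factor 2, corrected count 12.
sf, rf = background_correct(R_s=20, R_b=4, C_s=100, C_i=50)
print(f"\nbackground correction: sf = {sf}, corrected count R_f = {rf}")

d = linker_length_distribution(calls)
print(f"within-read distances between adjacent positive windows: {d.tolist()}")
# On real chromatin-footprint data these distances pile up near multiples of
# the nucleosome repeat length (~177 bp).
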