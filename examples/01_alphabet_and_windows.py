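"""Six-letter alphabet basics: enumeration, validity, class pooling and
site windows.

Run:  python examples/01_alphabet_and_windows.py
"""

from poremeth.alphabet import (
    collapse_to_class,
    enumerate_alphabet,
    is_valid_kmer,
    segment_read,
)

count, kmers = enumerate_alphabet(6)
valid = sum(1 for k in kmers if is_valid_kmer(k))
print(f"6-mers over {{A,C,G,T,M,Z}}: {count}  (valid methylation contexts: {valid})")
count4, _ = enumerate_alphabet(6, "ACGT")
print(f"standard four-letter 6-mers: {count4}")

for kmer in ("TAMGGG", "TAMAGG", "TZCACG", "TZCZCG"):
    if is_valid_kmer(kmer):
        cls = collapse_to_class(kmer)
        print(f"{kmer}: valid, class {cls.label}")
    else:
        print(f"{kmer}: invalid (M outside CpG context)")

# A read spanning 0-160 of a toy reference: CpG substrings get >= 10 bp
# CpG-free flanks; adenine windows tile 50 bp and drop the remainder.
ref = "T" * 60 + "CGTTCG" + "TA" * 47
windows = segment_read(ref, 0, 160, k=6)
for w in windows:
    print(f"{w.kind:15s} [{w.ref_start:3d}, {w.ref_end:3d})  "
          f"CpGs={w.n_cpg}  adenines={w.n_adenine}")
# The CpG substring covers both CpGs jointly (they are < 10 bp apart); the
# 50-bp tiles cover [0,150) with the 10-bp remainder dropped, and the first
# tile is omitted because it contains no adenine to test.
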