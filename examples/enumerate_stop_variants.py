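"""Enumerate every possible single-nucleotide edit at a stop codon.

Each stop codon admits 9 substitutions, 12 insertions and 3 deletions.
Edits whose first mutant codon is still a stop are "stop_retained" and have
no protein consequence; the rest are stop-loss (with NSD flagged when the
3'UTR offers no in-frame stop codon downstream).
"""

import stopext as se

t = se.validate(se.Transcript(id="demo", cds="ATGAAATGA", utr3="TTTCCATAAGG"))
print(f"transcript {t.id}: stop codon {t.stop_codon}, "
      f"protein {t.protein_length} aa, 3'UTR {len(t.utr3)} nt\n")

for v in se.enumerate_all(t):
    print(f"{v.kind:12s} {v.hgvs_c:18s} {v.hgvs_p:24s} {v.consequence}")

counts = se.stop_retained_counts()
print("\nstop-retained substitutions per codon (of 9):", counts)
print("Across all 27 substitutions,", sum(counts.values()),
      "are stop-retained; the rest extend the protein into the 3'UTR.")
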