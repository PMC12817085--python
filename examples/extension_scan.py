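"""Derive the C-terminal extension produced by a stop-loss variant.

The mutant codon contributes the residue at the old stop position; the
3'UTR is then scanned codon by codon for the nearest in-frame stop.  With
no such stop, the transcript is a nonstop-decay (NSD) substrate.
"""

import stopext as se

t = se.validate(se.Transcript(id="demo", cds="ATGTGA", utr3="TTTAAATAGCC"))

for v in se.enumerate_snvs(t):
    if v.consequence == "stop_retained":
        continue
    ext = se.extension_for_variant(t, v)
    print(f"{v.hgvs_c:14s} {v.hgvs_p:22s} residue={ext.substituted_aa} "
          f"extension={ext.peptide!r} ({ext.ext_len_codons} codons) "
          f"new_stop={ext.new_stop_codon}")

# An all-GC UTR cannot terminate translation: NSD
nsd = se.validate(se.Transcript(id="nsd", cds="ATGTGA", utr3="GCGCGCGCG"))
v = next(v for v in se.enumerate_snvs(nsd) if v.consequence != "stop_retained")
print("\nGC-only UTR:", se.extension_for_variant(nsd, v))
print("An NSD variant is not scored; it receives PVS1 in the evidence module.")
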