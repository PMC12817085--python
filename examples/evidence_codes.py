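"""Assign ACMG/AMP-style evidence codes to stop-loss variants.

The flowchart: NSD -> PVS1 (very strong, loss of function).  Otherwise the
extension is matched against known classified variants of the same
transcript: identical protein product -> PS1; identical extension but a
different residue at the old stop -> PM5; no match -> PM4 (length change).
A pathogenicity score >= 0.7 independently adds PP3.
"""

import stopext as se
from stopext.extension import ExtensionResult

# Known classified variants of one transcript: two pathogenic records with
# the same 35-residue extension but different residues at the old stop.
ext_pep = "LLAPGCWRKSAEDFYHIMNQTVLLAPGCWRKSAED"
db = se.KnownVariantDB([
    se.KnownVariant("ENST_DEMO", "R", ext_pep, "P", "p.Ter251ArgextTer36"),
    se.KnownVariant("ENST_DEMO", "S", ext_pep, "P", "p.Ter251SerextTer36"),
])

cases = {
    "identical protein (Arg)": ExtensionResult("R", ext_pep, 35, "TAA", False),
    "same extension, Cys at stop": ExtensionResult("C", ext_pep, 35, "TAA", False),
    "novel extension": ExtensionResult("K", "MST", 3, "TGA", False),
    "no downstream stop (NSD)": ExtensionResult("R", "GPA", 3, None, True),
}

for name, ext in cases.items():
    ev = se.assign_evidence(ext, score=0.95, db=db, transcript_id="ENST_DEMO")
    print(f"{name:30s} -> {sorted(ev.codes)}")
    for code, why in ev.rationale.items():
        print(f"   {code}: {why}")

print("\nB/LB cohort labeling rule (AF > 0.1% or homozygous):")
for af, hom in [(0.002, 0), (0.0001, 1), (0.0005, 0)]:
    print(f"  AF={af}, hom={hom} -> B/LB={se.label_by_frequency(af, hom)}")
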