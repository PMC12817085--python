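# Methods

This note records the scientific model behind `stopext`, the numerical and
design choices that were genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Biological model

A transcript is modelled in transcript space as a CDS ending in one of the
three canonical stop codons plus its 3′UTR. Only the standard nuclear
genetic code is supported; selenocysteine recoding and programmed
readthrough are out of scope, as are mRNA secondary-structure effects on
stop-codon selection — the model always uses the *nearest* downstream
in-frame stop. CDSs containing an internal in-frame stop codon are treated
as validation errors rather than silently truncated, since the package has
no basis for deciding which stop is real.

### Variant enumeration

For each stop codon position there are three alternative bases (9
substitutions per codon). Insertions are placed at the three
inter-nucleotide points that disrupt the codon read at the stop position —
before nt1, between nt1–nt2 and between nt2–nt3, each with 4 bases (12
insertions); an insertion after nt3 lies wholly in the 3′UTR and can never
change termination, so it is excluded. Deletions remove one of the three
stop-codon bases (3 per codon). This placement convention is isolated in
one function (`extension.mutant_reading`) because alternative HGVS-level
conventions exist for where an inserted base "belongs"; ours reproduces the
9/12/3 counts and treats downstream consequences identically.

For indels, the mutant read is reconstructed from the stop codon's first
base through the UTR. If the first mutant codon is again a stop, the edit
is stop-retained (a stop "resurrected" from UTR bases) and excluded from
scoring; otherwise the first mutant codon provides the residue at the old
stop position and scanning proceeds in the shifted frame (+1 for
insertions, −1 for deletions).

### Extension length convention

`ext_len_codons` counts codons translated from the UTR *strictly before*
the new stop; the substituted residue at the old stop position is reported
separately, and HGVS `extTer{M}` is emitted with `M = ext_len_codons + 1`
(the new Ter occupies the position `old + M`). Whether published extension
lengths include the substituted residue is ambiguous; under the alternative
convention every length feature shifts by exactly 1, which a forest is
insensitive to, but the convention is documented here and applied
uniformly. A trailing partial codon (<3 nt) can never terminate translation
and therefore counts toward the NSD determination.

The frameshift-distribution helper uses the convention that a +1 shift (one
base gained) pulls the final base of the original stop codon into the
downstream frame, while a −1 shift skips the first UTR base; under an iid
base model both frames have the same scan-length expectation, which is what
the cohort-level comparison exercises.

## Features

The 37-entry vector is fixed-order: 4 variant-level pass-through scores,
6 transcript features, 27 protein features. Choices worth recording:

- **Hydrophobicity scales.** Kyte–Doolittle is the canonical hydropathy
  index (span −4.5…+4.5, Ile = +4.5, Arg = −4.5). Several
  Miyazawa–Jernigan-derived hydrophobicity tables circulate; we embed the
  variant shipped by the R `Peptides` AAdata tables (contact-energy
  derived, all-positive, Phe/Met/Ile high), which is the table the R
  peptide-analysis ecosystem applies by default.
- **TANGO / CANYA** are external aggregation predictors and enter as
  pass-through columns; a hook accepts a per-residue TANGO profile and
  reduces it to its maximum.
- **Empty extensions** (a stop codon at UTR position 0) have all-zero
  composition counts and *missing* mean hydrophobicity — a mean over zero
  residues is undefined — which median imputation later fills.
- **3′UTR length and GC** are computed on the full annotated UTR, not only
  the translated part, so they are variant-independent transcript
  properties.
- Conservation scores for a stop codon are conceptually averaged over its
  three bases; since they are pass-through inputs the averaging happens
  upstream.

Median imputation is fitted on training rows only (per CV fold during
model selection) and the fitted medians are stored in the model archive, so
held-out data can never influence them.

## Classifier

The score is the ensemble average over trees; with scikit-learn's
classification forest each tree contributes its leaf's pathogenic-class
fraction, which matches the leaf-constant formulation exactly. `max_node`
is enforced as `max_leaf_nodes` (a cap on terminal leaves per tree) and
`mtry` as `max_features`. The grid is
{2, 5, 10, 15, 20} × {20, 50, 100, 200, 300, 400} × {5, 10, 20, 30}
(120 points) scored by mean out-of-fold AUROC over stratified 5-fold CV;
stratification is our choice (it stabilizes AUROC at cohort sizes of a few
hundred) since fold construction details are otherwise open. Ties are
broken toward smaller `ntree`, then smaller `max_node` (the cheaper,
lower-variance model). All randomness — folds, bootstrap, feature
subsampling — flows from one explicit seed. Defaults are the grid optimum
`mtry=20, ntree=200, max_node=30`.

AUROC uses the rank statistic with averaged ties; AUPRC uses the
step-interpolated average-precision form (no linear interpolation, which
overestimates PR area).

## Calibration

The two-component Gaussian mixture is fitted by EM (k-means
initialization, 10 restarts, best log-likelihood kept, seeded); components
are labeled by mean order. The likelihood ratio uses the *component
densities without mixing weights*, following the defining formula; a
weighted posterior-odds variant exists behind `posterior_odds` but is not
the default. Threshold solving: with equal variances
`x = (μ_B + μ_P)/2 + σ² ln(ratio)/(μ_P − μ_B)` in closed form; with
unequal variances the log-LR is quadratic in x and the root strictly
between the component means is selected, then polished with a bracketed
root-finder (tolerance 1e-14; self-consistency `LR(upper) = ratio` holds to
1e-9 in tests). A fit whose LR equation has no root between the means
raises with diagnostics rather than extrapolating.

The operational cutoffs 0.30/0.70 are shipped as named constants separate
from freshly solved thresholds: reproducing them exactly requires the full
transcriptome-wide score distribution, which is external data.

## Evidence assignment

PVS1 (NSD) terminates the flowchart. PS1 requires a byte-identical
extended protein — extension peptide *and* substituted residue — from a
P/LP record of the same transcript; PM5 requires a byte-identical extension
with a different substituted residue; otherwise PM4. When both PS1- and
PM5-type matches exist, PS1 wins (the stronger, more specific evidence).
PP3 attaches independently at score ≥ 0.7, with a caution string when an
optional inheritance-mode flag marks the gene recessive. Evidence codes
are proposed, never combined into a final classification.

## Synthetic data

The generator is the fixture factory for every test. Study conditions:
620 training variants at a 1:1 class ratio and an imbalanced 558-variant
evaluation set (187 pathogenic / 371 benign), mirroring the scale of real
curated stop-loss cohorts; stop-codon usage TGA 49.2% / TAA 28.4% /
TAG 22.4%; log-normal UTR lengths (median ≈ 545 nt of tail beyond the
planted extension); beta-distributed per-transcript GC centred on 0.45.

Planted contrasts (all recorded in `EXPECTED_SIGNS` and asserted by the
suite): pathogenic rows get 2.2× longer extensions, residue composition
tilted toward Leu/Pro/Ala/Cys (benign toward Ser/Lys/Glu/Tyr, a 3:1
up-weight), GC-richer synonymous codons and tails (+0.10), 1.6× longer UTR
tails, +1.2 SD shifts on the four score proxies, +0.5 on mRNA-stability Z,
higher constraint (lower LOEUF, higher pLI/s_het), IDP rates 10.0% vs
1.3%, and rarer allele-frequency proxies. Aggregation proxies ride on the
extension's hydrophobicity plus noise. 5% of annotation cells are dropped
to exercise imputation. A `null()` spec zeroes every effect, under which
cross-validated AUROC sits at chance level.

Extensions are built by back-translating a sampled peptide and appending a
usage-sampled stop codon, so every cohort row flows through the *real*
enumeration → extension → feature path and all production invariants hold.

What passing these tests shows: the pipeline is internally consistent,
leak-free, and able to recover a planted signal of realistic shape and
size. What it does not show: performance on real cohorts, where the
features are correlated in ways the generator does not emulate (real
conservation scores, real UTR sequence constraint, shared transcripts
between variants).

## Problem sizes and numerical notes

Simulation-based checks use cohorts of 300–620 rows, 10 seeds for the
null-label check, 1,000 random UTRs for the scan oracle, 50,000 draws for
the Monte-Carlo scan-length comparison (within 1% of the analytic 64/3),
and n = 2,000 for mixture recovery (±0.02 on component means) — sizes at
which each check is stable yet the full suite runs in a couple of minutes
on one CPU.

The expected scan length uses the geometric "codons until first success"
model, whose mean 1/p = 64/3 ≈ 21.3 at uniform composition is the value
consistent with an iid base model; the count includes the terminating stop
codon, while per-transcript extension lengths exclude it (hence summaries
compare `mean + 1` against 64/3).

## Known limitations

- Genome-coordinate annotation (VEP/ANNOVAR-style), multi-nucleotide
  variants and non-canonical isoforms are out of scope; inputs are
  transcript-space.
- Conservation/constraint/aggregation scores are never recomputed; absent
  annotations fall back to median imputation, which flattens their signal.
- The classifier cannot distinguish loss- from gain-of-function
  mechanisms; scores are evidence of impact, not mechanism.
- Thresholds calibrated on small or unimodal score sets are unreliable;
  the mixture fit raises on degenerate data but cannot detect mild
  misspecification.
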