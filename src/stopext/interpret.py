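"""ACMG/AMP-style evidence assignment for stop-loss variants.

The flowchart: a variant whose transcript has no downstream in-frame stop
codon triggers nonstop decay and receives PVS1 (very strong loss-of-function
evidence), terminating the assessment.  Otherwise the C-terminal extension
is compared against known classified variants: an extension identical to an
established pathogenic one, including the residue at the old stop position,
earns PS1; identical except for that single residue earns PM5; with no
match, the protein-length change itself earns PM4.  Independently of the
match branch, a pathogenicity score >= 0.7 adds PP3 as supporting
computational evidence.  Evidence codes are proposed, not combined into a
final classification -- combining criteria is the clinical workflow's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .extension import ExtensionResult

#: Score cutoff above which PP3 (supporting computational evidence) applies.
PP3_SCORE_CUTOFF = 0.7


class InterpretError(ValueError):
    pass


@dataclass(frozen=True)
class KnownVariant:
    transcript_id: str
    substituted_aa: str
    peptide: str
    classification: str  # P | LP | B | LB | VUS
    hgvs_p: str = ""


class KnownVariantDB:
    """Classified stop-loss variants keyed by transcript and protein change."""

    def __init__(self, records: list[KnownVariant] | None = None):
        self._records: list[KnownVariant] = []
        seen: dict[tuple[str, str], str] = {}
        for r in records or []:
            k = (r.transcript_id, r.substituted_aa)
            if k in seen and seen[k] != r.classification:
                raise InterpretError(
                    f"conflicting classifications for {k}: "
                    f"{seen[k]} vs {r.classification}"
                )
            seen[k] = r.classification
            self._records.append(r)

    def __len__(self) -> int:
        return len(self._records)

    def pathogenic_in(self, transcript_id: str) -> list[KnownVariant]:
        return [
            r
            for r in self._records
            if r.transcript_id == transcript_id and r.classification in ("P", "LP")
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownVariantDB":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(
            [
                KnownVariant(
                    r["transcript_id"],
                    r["substituted_aa"],
                    r["peptide"],
                    r["classification"],
                    r.get("hgvs_p", ""),
                )
                for _, r in df.iterrows()
            ]
        )


@dataclass(frozen=True)
class EvidenceAssignment:
    codes: frozenset[str]
    rationale: dict = field(default_factory=dict, compare=False)
    warnings: tuple[str, ...] = ()


def assign_evidence(
    ext: ExtensionResult,
    score: float | None,
    db: KnownVariantDB,
    transcript_id: str,
    recessive: bool = False,
) -> EvidenceAssignment:
    """Walk the evidence flowchart for one stop-loss variant.

    ``score`` may be None (e.g. unscored variants); PP3 then never applies.
    ``recessive`` is an optional pass-through flag from an inheritance-mode
    column; it attaches a caution to PP3, since supporting computational
    evidence for heterozygous variants in recessive genes is
    context-dependent.
    """
    if ext.nsd:
        return EvidenceAssignment(
            frozenset({"PVS1"}),
            {"PVS1": "no in-frame stop codon in the 3'UTR: nonstop decay "
                     "degrades the transcript (loss of function)"},
        )

    codes: set[str] = set()
    rationale: dict[str, str] = {}
    warnings: tuple[str, ...] = ()

    same_protein = [
        r for r in db.pathogenic_in(transcript_id)
        if r.peptide == ext.peptide and r.substituted_aa == ext.substituted_aa
    ]
    same_extension = [
        r for r in db.pathogenic_in(transcript_id)
        if r.peptide == ext.peptide and r.substituted_aa != ext.substituted_aa
    ]
    if same_protein:
        codes.add("PS1")
        rationale["PS1"] = (
            "C-terminal extension identical to established pathogenic variant "
            f"{same_protein[0].hgvs_p or same_protein[0].substituted_aa}"
        )
    elif same_extension:
        codes.add("PM5")
        rationale["PM5"] = (
            "extension identical to an established pathogenic variant except "
            "for the amino acid at the stop codon "
            f"({ext.substituted_aa} vs {same_extension[0].substituted_aa})"
        )
    else:
        codes.add("PM4")
        rationale["PM4"] = "protein length change (C-terminal extension)"

    if score is not None:
        if not 0.0 <= score <= 1.0:
            raise InterpretError(f"score must lie in [0, 1], got {score}")
        if score >= PP3_SCORE_CUTOFF:
            codes.add("PP3")
            rationale["PP3"] = f"pathogenicity score {score:.3f} >= {PP3_SCORE_CUTOFF}"
            if recessive:
                warnings = (
                    "PP3 in a recessive gene: apply in a context-dependent "
                    "manner (zygosity and disease mechanism)",
                )
    return EvidenceAssignment(frozenset(codes), rationale, warnings)


def label_by_frequency(af_max: float, n_hom: int) -> bool:
    """Benign/likely-benign labeling rule for training cohorts.

    True iff the maximum population allele frequency exceeds 0.1% or the
    variant has been observed in the homozygous state.
    """
    if not 0.0 <= af_max <= 1.0:
        raise InterpretError(f"allele frequency must lie in [0, 1], got {af_max}")
    if n_hom < 0:
        raise InterpretError("homozygote count must be non-negative")
    return af_max > 0.001 or n_hom >= 1


def write_evidence_tsv(rows: list[tuple[str, EvidenceAssignment]], path: str | Path) -> None:
    """One row per variant: id, comma-joined codes, warnings."""
    with open(path, "w") as fh:
        fh.write("variant_id\tcodes\twarnings\n")
        for vid, ev in rows:
            fh.write(
                f"{vid}\t{','.join(sorted(ev.codes))}\t"
                f"{';'.join(ev.warnings) or '.'}\n"
            )
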