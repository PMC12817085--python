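"""Enumeration of all possible single-nucleotide edits at a stop codon.

Each stop codon admits exactly 9 substitutions (3 positions x 3 alternative
bases), 12 single-base insertions (4 bases x 3 insertion points that disrupt
the codon -- an insertion after the third base lands in the 3'UTR and never
alters termination) and 3 single-base deletions (one per position).  Edits
whose first mutant codon is still a stop codon are classified stop-retained
and excluded from scoring; the rest are stop-loss, with nonstop decay (NSD)
flagged when the shifted or unshifted downstream read contains no in-frame
stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.SeqUtils import seq3

from .extension import ExtensionResult, extension_for_variant, mutant_reading, scan_for_stop
from .transcripts import GENETIC_CODE, STOP_CODONS, Transcript

_BASES = "ACGT"


@dataclass(frozen=True)
class StopVariant:
    """A single-nucleotide edit to a transcript's stop codon.

    ``position`` is the 1-based nucleotide of the stop codon (for insertions:
    the nucleotide the new base is inserted before).  ``ref``/``alt`` are the
    replaced/introduced base; insertions have ``ref == ""`` and deletions
    ``alt == ""``.
    """

    transcript_id: str
    kind: str  # substitution | insertion | deletion
    position: int
    ref: str
    alt: str
    consequence: str  # stop_retained | stop_loss | stop_loss_nsd
    hgvs_c: str
    hgvs_p: str
    new_aa: str | None = None  # residue at the old stop position (stop-loss only)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.kind, self.position, self.alt)


def _hgvs_c(t: Transcript, kind: str, position: int, ref: str, alt: str) -> str:
    start = len(t.cds) - 2  # 1-based CDS coordinate of the stop codon's first base
    if kind == "substitution":
        return f"{t.id}:c.{start + position - 1}{ref}>{alt}"
    if kind == "insertion":
        left = start + position - 2
        return f"{t.id}:c.{left}_{left + 1}ins{alt}"
    return f"{t.id}:c.{start + position - 1}del"


def _hgvs_p(t: Transcript, consequence: str, new_aa: str | None, ext: ExtensionResult | None) -> str:
    ter = t.protein_length + 1
    if consequence == "stop_retained":
        return f"p.Ter{ter}="
    aa3 = seq3(new_aa) if new_aa else "?"
    if ext is None or ext.nsd:
        return f"p.Ter{ter}{aa3}extTer?"
    # the new Ter sits ext_len + 1 codons beyond the original stop position
    return f"p.Ter{ter}{aa3}extTer{ext.ext_len_codons + 1}"


def _classify(t: Transcript, kind: str, position: int, ref: str, alt: str) -> StopVariant:
    edited, _ = mutant_reading(t.stop_codon, kind, position, alt)
    read = edited + t.utr3
    hgvs_c = _hgvs_c(t, kind, position, ref, alt)
    if len(read) >= 3 and read[:3] in STOP_CODONS:
        return StopVariant(
            t.id, kind, position, ref, alt, "stop_retained", hgvs_c,
            _hgvs_p(t, "stop_retained", None, None),
        )
    new_aa = GENETIC_CODE[read[:3]] if len(read) >= 3 else None
    nsd = len(read) < 3 or scan_for_stop(read[3:]) is None
    consequence = "stop_loss_nsd" if nsd else "stop_loss"
    v = StopVariant(t.id, kind, position, ref, alt, consequence, hgvs_c, "", new_aa)
    ext = extension_for_variant(t, v)
    return StopVariant(
        t.id, kind, position, ref, alt, consequence, hgvs_c,
        _hgvs_p(t, consequence, new_aa, ext), new_aa,
    )


def classify_indel(
    stop_codon: str, kind: str, position: int, alt: str, utr3: str
) -> tuple[str, str, int]:
    """Classify a single-base indel at a stop codon.

    Reconstructs the mutant read from the stop codon's first base through the
    3'UTR.  Returns ``(consequence, first_mutant_codon, frame_offset)``;
    downstream scanning proceeds in the shifted frame over the remainder.
    """
    edited, offset = mutant_reading(stop_codon, kind, position, alt)
    read = edited + utr3
    if len(read) < 3:
        return "stop_loss_nsd", read, offset
    first = read[:3]
    if first in STOP_CODONS:
        return "stop_retained", first, offset
    nsd = scan_for_stop(read[3:]) is None
    return ("stop_loss_nsd" if nsd else "stop_loss"), first, offset


def enumerate_snvs(t: Transcript) -> list[StopVariant]:
    """All 9 single-nucleotide substitutions at the stop codon.

    A substitution is stop-retained iff the mutated codon is itself one of
    TAA/TAG/TGA (2 of 9 for TAA, 1 of 9 each for TAG and TGA).
    """
    out = []
    for pos in (1, 2, 3):
        ref = t.stop_codon[pos - 1]
        for alt in _BASES:
            if alt != ref:
                out.append(_classify(t, "substitution", pos, ref, alt))
    return out


def enumerate_insertions(t: Transcript) -> list[StopVariant]:
    """All 12 single-nucleotide insertions that disrupt the stop codon."""
    return [
        _classify(t, "insertion", pos, "", base)
        for pos in (1, 2, 3)
        for base in _BASES
    ]


def enumerate_deletions(t: Transcript) -> list[StopVariant]:
    """All 3 single-nucleotide deletions within the stop codon."""
    return [
        _classify(t, "deletion", pos, t.stop_codon[pos - 1], "")
        for pos in (1, 2, 3)
    ]


def enumerate_all(t: Transcript) -> list[StopVariant]:
    """All 24 possible single-nucleotide edits at the stop codon (9+12+3)."""
    return enumerate_snvs(t) + enumerate_insertions(t) + enumerate_deletions(t)


def stop_retained_counts() -> dict[str, int]:
    """Per-stop-codon count of stop-retained substitutions among the 9.

    Computed by live enumeration (not hard-coded): 2 for TAA, 1 for TAG and
    TGA; 4 of the 27 substitutions in total.
    """
    counts = {}
    for stop in STOP_CODONS:
        t = Transcript(id=f"_{stop}", cds="ATG" + stop, utr3="TAA")
        counts[stop] = sum(
            v.consequence == "stop_retained" for v in enumerate_snvs(t)
        )
    return counts


def write_variant_tsv(
    transcripts: list[Transcript], path: str | Path
) -> int:
    """Enumerate every edit for every transcript and write one TSV row each.

    Columns: transcript_id, kind, hgvs_c, hgvs_p, consequence, new_aa,
    extension_len, nsd_flag.  Missing values are written as ".".
    Returns the number of rows written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tkind\thgvs_c\thgvs_p\tconsequence\tnew_aa\t"
            "extension_len\tnsd_flag\n"
        )
        for t in transcripts:
            for v in enumerate_all(t):
                if v.consequence == "stop_retained":
                    ext_len, nsd = ".", "0"
                else:
                    ext = extension_for_variant(t, v)
                    ext_len = "." if ext.nsd else str(ext.ext_len_codons)
                    nsd = str(int(ext.nsd))
                fh.write(
                    f"{v.transcript_id}\t{v.kind}\t{v.hgvs_c}\t{v.hgvs_p}\t"
                    f"{v.consequence}\t{v.new_aa or '.'}\t{ext_len}\t{nsd}\n"
                )
                n += 1
    return n
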