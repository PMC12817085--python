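"""C-terminal extension computation for stop-loss variants.

When a stop codon is lost, translation continues into the 3'UTR until the
nearest downstream in-frame stop codon; the translated stretch is the
C-terminal extension.  If no in-frame stop exists, the ribosome reaches the
end of the transcript and the mRNA becomes a nonstop-decay (NSD) substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .transcripts import GENETIC_CODE, STOP_CODONS, Transcript, translate

if TYPE_CHECKING:  # pragma: no cover
    from .variants import StopVariant


class ExtensionError(ValueError):
    """Raised on contract violations (e.g. extending a stop-retained variant)."""


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of scanning the 3'UTR downstream of a lost stop codon.

    Attributes
    ----------
    substituted_aa : str or None
        One-letter amino acid now encoded at the original stop position
        (None for the frame-shift distribution helper, which models no
        specific variant).
    peptide : str
        Extension peptide translated from the scanned region; excludes the
        substituted residue and the new stop codon.
    ext_len_codons : int
        Number of codons translated strictly before the new stop codon;
        equals ``len(peptide)``.
    new_stop_codon : str or None
        The terminating stop codon (TAA/TAG/TGA), or None under NSD.
    nsd : bool
        True when no in-frame stop codon exists in the scanned region.
    frame_offset : int
        0 for substitutions, +1 for single-base insertions, -1 for
        single-base deletions (the shift of the downstream reading frame).
    """

    substituted_aa: str | None
    peptide: str
    ext_len_codons: int
    new_stop_codon: str | None
    nsd: bool
    frame_offset: int = 0

    def __post_init__(self) -> None:
        assert self.nsd == (self.new_stop_codon is None)
        assert len(self.peptide) == self.ext_len_codons


def scan_for_stop(seq: str, frame_offset: int = 0) -> int | None:
    """Find the first in-frame stop codon in ``seq``, read in triplets from 0.

    For the shifted frames (+1/-1) the caller passes the already
    frame-shifted suffix (as produced by the indel reconstruction); scanning
    always proceeds over complete codons from position 0.  A trailing partial
    codon (<3 nt) can never terminate translation.

    Returns the 0-based codon index of the first stop codon, or None when no
    in-frame stop exists (NSD).
    """
    if frame_offset not in (0, 1, -1):
        raise ExtensionError(f"frame_offset must be 0, +1 or -1, got {frame_offset}")
    seq = seq.upper()
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i // 3
    return None


def _scan_result(
    scanned: str, substituted_aa: str | None, frame_offset: int
) -> ExtensionResult:
    idx = scan_for_stop(scanned)
    if idx is None:
        n = len(scanned) // 3
        peptide, _ = translate(scanned[: 3 * n])
        return ExtensionResult(substituted_aa, peptide, n, None, True, frame_offset)
    peptide, _ = translate(scanned[: 3 * idx])
    new_stop = scanned[3 * idx : 3 * idx + 3]
    return ExtensionResult(substituted_aa, peptide, idx, new_stop, False, frame_offset)


def mutant_reading(
    stop_codon: str, kind: str, position: int, alt: str
) -> tuple[str, int]:
    """Reconstruct the edited stop-codon region for an edit at the stop codon.

    Returns the edited bases (4 for an insertion, 3 for a substitution, 2 for
    a deletion) and the downstream frame offset (+1 insertion, -1 deletion,
    0 substitution).  ``position`` is 1..3 within the stop codon; for
    insertions it names the nucleotide the new base is inserted *before*.
    """
    if kind == "substitution":
        edited = stop_codon[: position - 1] + alt + stop_codon[position:]
        return edited, 0
    if kind == "insertion":
        edited = stop_codon[: position - 1] + alt + stop_codon[position - 1 :]
        return edited, 1
    if kind == "deletion":
        edited = stop_codon[: position - 1] + stop_codon[position:]
        return edited, -1
    raise ExtensionError(f"unknown variant kind {kind!r}")


def extension_for_variant(t: Transcript, v: "StopVariant") -> ExtensionResult:
    """Compute the C-terminal extension produced by a stop-loss variant.

    For substitutions the new residue at the old stop position is translated
    from the mutant codon and the 3'UTR is scanned in frame 0.  For indels
    the mutant sequence is reconstructed from the stop codon's first base
    through the UTR; the first mutant codon provides the substituted residue
    and scanning proceeds in the shifted frame.

    Raises
    ------
    ExtensionError
        For stop-retained variants (nothing to extend).
    """
    if v.consequence == "stop_retained":
        raise ExtensionError(f"{v.hgvs_c}: stop-retained variant has no extension")
    edited, offset = mutant_reading(t.stop_codon, v.kind, v.position, v.alt)
    read = edited + t.utr3
    if len(read) < 3:
        # deletion with an empty/one-base UTR: no complete codon at all
        return ExtensionResult(None, "", 0, None, True, offset)
    first, scanned = read[:3], read[3:]
    aa = GENETIC_CODE[first]
    if aa == "*":
        raise ExtensionError(f"{v.hgvs_c}: stop-retained variant has no extension")
    return _scan_result(scanned, aa, offset)


def frameshift_extension(t: Transcript, shift: int) -> ExtensionResult:
    """Scan the UTR in a shifted reading frame (extension-length helper).

    Models the downstream reading frame after a net single-base frameshift at
    the stop codon: a +1 shift (one base gained) pulls the final base of the
    original stop codon into the downstream frame, a -1 shift (one base lost)
    skips the first UTR base.  Used for cohort-level extension-length
    distributions; not scored.
    """
    if shift == 1:
        scanned = t.cds[-1] + t.utr3
    elif shift == -1:
        scanned = t.utr3[1:]
    else:
        raise ExtensionError("shift must be +1 or -1; use scan_for_stop for frame 0")
    return _scan_result(scanned, None, shift)
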