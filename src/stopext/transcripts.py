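"""Transcript data model, validation and genetic-code translation.

A transcript is represented in transcript space (5'->3', sense strand): a
coding sequence that ends in one of the three canonical stop codons
(TAA/TAG/TGA) plus the 3' untranslated region that follows it.  Genomic
coordinates, strand handling and isoform selection (e.g. picking the MANE
transcript per gene) happen upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: The three canonical stop codons of the standard nuclear genetic code.
STOP_CODONS: tuple[str, str, str] = ("TAA", "TAG", "TGA")

_VALID_BASES = frozenset("ACGT")

#: Total map of the 64 codons to one-letter amino acids, with "*" for the
#: three stop codons.  Built from the standard (id 1) codon table; only the
#: standard nuclear code is supported -- selenocysteine insertion and
#: programmed readthrough recoding are not modelled.
GENETIC_CODE: dict[str, str] = {
    **CodonTable.unambiguous_dna_by_id[1].forward_table,
    **{c: "*" for c in CodonTable.unambiguous_dna_by_id[1].stop_codons},
}

assert len(GENETIC_CODE) == 64
assert sorted(c for c, aa in GENETIC_CODE.items() if aa == "*") == sorted(STOP_CODONS)


class TranscriptError(ValueError):
    """Raised when a transcript or sequence violates its invariants."""


@dataclass(frozen=True)
class Transcript:
    """A coding sequence (including its terminal stop codon) and its 3'UTR.

    Attributes
    ----------
    id : str
        Transcript identifier (e.g. an Ensembl transcript id).
    cds : str
        Coding sequence, uppercase A/C/G/T, length a multiple of 3, ending in
        a canonical stop codon.
    utr3 : str
        3' untranslated region immediately downstream of the stop codon; may
        be empty (such transcripts can be modelled but are excluded from
        scoring).
    gene_id : str, optional
    """

    id: str
    cds: str
    utr3: str = ""
    gene_id: str | None = None
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper())
        object.__setattr__(self, "utr3", self.utr3.upper())

    @property
    def stop_codon(self) -> str:
        """The terminal stop codon (last three bases of the CDS)."""
        return self.cds[-3:]

    @property
    def protein_length(self) -> int:
        """Length of the encoded protein in residues, stop codon excluded."""
        return len(self.cds) // 3 - 1


def _check_bases(seq: str, what: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise TranscriptError(
            f"{what} contains non-ACGT characters: {sorted(bad)} "
            "(ambiguity codes are rejected)"
        )


def validate(t: Transcript) -> Transcript:
    """Validate a transcript against its invariants.

    Returns the transcript unchanged on success; a transcript with an empty
    3'UTR is valid but carries an ``"empty_utr3"`` warning flag (it is
    excluded from scoring downstream, since no extension can terminate).

    Raises
    ------
    TranscriptError
        If the CDS length is not a positive multiple of 3, the CDS does not
        end in a canonical stop codon, the CDS contains an internal in-frame
        stop codon, or either sequence contains non-ACGT characters.
    """
    _check_bases(t.cds, f"CDS of {t.id!r}")
    _check_bases(t.utr3, f"3'UTR of {t.id!r}")
    if len(t.cds) < 3 or len(t.cds) % 3 != 0:
        raise TranscriptError(
            f"CDS of {t.id!r} has length {len(t.cds)}, not a positive multiple of 3"
        )
    if t.stop_codon not in STOP_CODONS:
        raise TranscriptError(
            f"CDS of {t.id!r} ends in {t.stop_codon!r}, not a canonical stop codon"
        )
    for i in range(0, len(t.cds) - 3, 3):
        if t.cds[i : i + 3] in STOP_CODONS:
            raise TranscriptError(
                f"CDS of {t.id!r} contains an internal in-frame stop codon "
                f"at codon {i // 3 + 1}"
            )
    if not t.utr3:
        return replace(t, warnings=t.warnings + ("empty_utr3",))
    return t


def translate(seq: str) -> tuple[str, bool]:
    """Translate an in-frame DNA sequence with the standard genetic code.

    Translation stops at (and excludes) the first stop codon encountered.

    Parameters
    ----------
    seq : str
        DNA sequence whose length is a multiple of 3.

    Returns
    -------
    peptide : str
        One-letter amino-acid string.
    stop_reached : bool
        True when a stop codon terminated translation.
    """
    seq = seq.upper()
    _check_bases(seq, "sequence")
    if len(seq) % 3 != 0:
        raise TranscriptError(f"sequence length {len(seq)} is not a multiple of 3")
    peptide: list[str] = []
    for i in range(0, len(seq), 3):
        aa = GENETIC_CODE[seq[i : i + 3]]
        if aa == "*":
            return "".join(peptide), True
        peptide.append(aa)
    return "".join(peptide), False


# ---------------------------------------------------------------------------
# readers


def read_fasta_pair(cds_path: str | Path, utr_path: str | Path) -> list[Transcript]:
    """Read transcripts from two FASTA files keyed by identical record ids.

    Record ids must match exactly between the two files; ids present in only
    one file are dropped with a logged count.  Every returned transcript has
    passed :func:`validate`.
    """
    cds = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_path), "fasta")}
    utr = {r.id: str(r.seq) for r in SeqIO.parse(str(utr_path), "fasta")}
    shared = [k for k in cds if k in utr]
    dropped = (set(cds) | set(utr)) - set(shared)
    if dropped:
        logger.warning("dropped %d unmatched record ids", len(dropped))
    return [validate(Transcript(id=k, cds=cds[k], utr3=utr[k])) for k in shared]


def read_transcript_tsv(path: str | Path) -> list[Transcript]:
    """Read transcripts from a 3-column TSV (id, cds, utr3; header row)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "cds", "utr3"}
    if not required.issubset(df.columns):
        raise TranscriptError(f"transcript TSV must have columns {sorted(required)}")
    return [
        validate(Transcript(id=row.id, cds=row.cds, utr3=row.utr3))
        for row in df.itertuples(index=False)
    ]


def write_transcript_tsv(transcripts: list[Transcript], path: str | Path) -> None:
    """Write transcripts as a 3-column TSV readable by :func:`read_transcript_tsv`."""
    with open(path, "w") as fh:
        fh.write("id\tcds\tutr3\n")
        for t in transcripts:
            fh.write(f"{t.id}\t{t.cds}\t{t.utr3}\n")
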