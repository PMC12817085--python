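"""Assembly of the 37-dimensional feature vector for stop-loss variants.

The vector X = [V1..V4, T1..T6, P1..P27] combines four variant-level
prediction/conservation scores (pass-through annotations), six transcript
features (3'UTR length and GC, mRNA-stability Z, pLI, LOEUF, s_het) and 27
protein features of the C-terminal extension (original protein length,
extension length, the 20 amino-acid counts, mean Kyte-Doolittle and
Miyazawa-Jernigan hydrophobicity, TANGO max, CANYA, and a curated-IDP flag).
Conservation, constraint and aggregation scores are externally computed and
enter as annotation columns; they are never recomputed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .extension import ExtensionResult
from .transcripts import Transcript
from .variants import StopVariant

#: One-letter amino acids in the fixed registry order used for counts.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle (1982) hydropathy index, spanning [-4.5, +4.5].
KD_SCALE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Miyazawa-Jernigan (1985) contact-energy-derived hydrophobicity, as
#: shipped by the R "Peptides" AAdata tables (higher = more hydrophobic).
MJ_SCALE: dict[str, float] = {
    "A": 5.33, "R": 4.18, "N": 3.71, "D": 3.59, "C": 7.93,
    "Q": 3.87, "E": 3.65, "G": 4.48, "H": 5.10, "I": 8.83,
    "L": 8.47, "K": 2.95, "M": 8.95, "F": 9.03, "P": 3.87,
    "S": 4.09, "T": 4.49, "W": 7.66, "Y": 5.89, "V": 7.63,
}

#: Canonical feature order of the 37-entry vector.
FEATURE_NAMES: tuple[str, ...] = (
    # V1-V4: variant-level prediction / conservation scores (pass-through)
    "CADD", "GERP", "PhyloP100", "PhastCons100",
    # T1-T6: transcript-level features
    "utr3_length", "utr3_gc", "mrna_stability_z", "pLI", "LOEUF", "s_het",
    # P1-P2: protein / extension lengths
    "protein_length", "ext_length",
    # P3-P22: amino-acid counts of the extension peptide
    *[f"aa_{a}" for a in AMINO_ACIDS],
    # P23-P27: hydrophobicity, aggregation and disorder
    "kd_mean", "mj_mean", "tango_max", "canya", "idp_flag",
)

assert len(FEATURE_NAMES) == 37


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    """Externally computed per-variant and per-gene annotation scores.

    All fields may be missing (None); missing values are median-imputed at
    training/prediction time.  ``tango_profile`` optionally carries a
    per-residue TANGO trace, reduced to its maximum.
    """

    cadd: float | None = None
    gerp: float | None = None
    phylop100: float | None = None
    phastcons100: float | None = None
    mrna_stability_z: float | None = None
    pli: float | None = None
    loeuf: float | None = None
    s_het: float | None = None
    tango_max: float | None = None
    canya: float | None = None
    idp_flag: int | None = None
    tango_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise FeatureError(f"pLI must lie in [0, 1], got {self.pli}")
        if self.idp_flag is not None and self.idp_flag not in (0, 1):
            raise FeatureError(f"idp_flag must be 0 or 1, got {self.idp_flag}")

    def resolved_tango(self) -> float | None:
        """TANGO feature: the maximum per-residue score, when a profile is given."""
        if self.tango_profile is not None and len(self.tango_profile) > 0:
            return float(max(self.tango_profile))
        return self.tango_max


def gc_content(seq: str) -> float:
    """GC content of a DNA sequence, in percent."""
    if not seq:
        raise FeatureError("GC content of an empty sequence is undefined")
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def aa_counts(peptide: str) -> dict[str, int]:
    """Counts of each of the 20 amino acids in a peptide (sum == length)."""
    unknown = set(peptide) - set(AMINO_ACIDS)
    if unknown:
        raise FeatureError(f"unknown amino acids {sorted(unknown)}")
    return {a: peptide.count(a) for a in AMINO_ACIDS}


def mean_hydrophobicity(peptide: str, scale: dict[str, float]) -> float:
    """Arithmetic mean of per-residue scale values; NaN for an empty peptide.

    The empty case (a zero-length extension) has no defined mean and is left
    missing for median imputation.
    """
    if not peptide:
        return math.nan
    unknown = set(peptide) - set(scale)
    if unknown:
        raise FeatureError(f"unknown amino acids {sorted(unknown)}")
    return sum(scale[a] for a in peptide) / len(peptide)


def assemble_features(
    t: Transcript,
    v: StopVariant,
    ext: ExtensionResult,
    ann: AnnotationRecord | None = None,
) -> dict[str, float]:
    """Build the 37-entry feature vector for one scored stop-loss variant.

    NSD variants are not scored (they follow the loss-of-function evidence
    path in the interpretation module) and raise :class:`FeatureError`.
    Unavailable annotations are NaN until imputation.  UTR length and GC are
    computed on the full annotated 3'UTR, not only the translated portion.
    """
    if v.consequence not in ("stop_loss", "stop_loss_nsd"):
        raise FeatureError(f"{v.hgvs_c}: only stop-loss variants are scored")
    if ext.nsd:
        raise FeatureError(
            f"{v.hgvs_c}: NSD variant is not scored; assign PVS1 via the "
            "interpretation module instead"
        )
    ann = ann or AnnotationRecord()

    def miss(x: float | int | None) -> float:
        return math.nan if x is None else float(x)

    row: dict[str, float] = {
        "CADD": miss(ann.cadd),
        "GERP": miss(ann.gerp),
        "PhyloP100": miss(ann.phylop100),
        "PhastCons100": miss(ann.phastcons100),
        "utr3_length": float(len(t.utr3)),
        "utr3_gc": gc_content(t.utr3),
        "mrna_stability_z": miss(ann.mrna_stability_z),
        "pLI": miss(ann.pli),
        "LOEUF": miss(ann.loeuf),
        "s_het": miss(ann.s_het),
        "protein_length": float(t.protein_length),
        "ext_length": float(ext.ext_len_codons),
        "kd_mean": mean_hydrophobicity(ext.peptide, KD_SCALE),
        "mj_mean": mean_hydrophobicity(ext.peptide, MJ_SCALE),
        "tango_max": miss(ann.resolved_tango()),
        "canya": miss(ann.canya),
        "idp_flag": miss(ann.idp_flag),
    }
    for a, c in aa_counts(ext.peptide).items():
        row[f"aa_{a}"] = float(c)
    return {name: row[name] for name in FEATURE_NAMES}


def feature_frame(rows: Iterable[dict[str, float]], index: Sequence | None = None) -> pd.DataFrame:
    """Stack assembled vectors into a feature matrix in canonical order."""
    df = pd.DataFrame(list(rows), index=index)
    return df.reindex(columns=list(FEATURE_NAMES))


def impute_median(
    table: pd.DataFrame, fit_rows: Sequence[bool] | pd.Index | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-impute missing values, with medians fitted on ``fit_rows`` only.

    ``fit_rows`` defaults to all rows; pass the training-fold mask (or index)
    so that held-out rows never influence the medians.  Returns the imputed
    table and the stored medians for reuse at prediction time.

    Raises
    ------
    FeatureError
        If any column is entirely missing within the fitting rows.
    """
    fit = table if fit_rows is None else table.loc[fit_rows]
    medians = fit.median(axis=0, skipna=True)
    all_missing = medians.index[medians.isna()]
    if len(all_missing):
        raise FeatureError(
            f"columns entirely missing in the fitting rows: {list(all_missing)}"
        )
    return table.fillna(medians), medians


def apply_medians(table: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    """Impute a new table with medians stored at training time."""
    return table.fillna(medians)


def write_feature_tsv(df: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV ('.' for missing), round-trippable."""
    df.to_csv(path, sep="\t", na_rep=".", index=True, index_label="variant_id")


def read_feature_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=".", index_col="variant_id")
    return df


def read_annotation_tsv(path) -> dict[str, AnnotationRecord]:
    """Read per-variant/per-gene annotations keyed by the first id column.

    Recognized columns match :class:`AnnotationRecord` field names; unknown
    columns are ignored with a logged warning.
    """
    import logging

    df = pd.read_csv(path, sep="\t", na_values=".")
    key_col = df.columns[0]
    fields = {f for f in AnnotationRecord.__dataclass_fields__ if f != "tango_profile"}
    unknown = [c for c in df.columns[1:] if c not in fields]
    if unknown:
        logging.getLogger(__name__).warning("ignoring unknown columns %s", unknown)
    out = {}
    for _, r in df.iterrows():
        kwargs = {}
        for f in fields:
            if f in df.columns and pd.notna(r[f]):
                kwargs[f] = int(r[f]) if f == "idp_flag" else float(r[f])
        out[str(r[key_col])] = AnnotationRecord(**kwargs)
    return out
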