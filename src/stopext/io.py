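"""Tabular and VCF plumbing shared by the CLI and the library.

TSV is the canonical tabular dialect: tab-separated, header row mandatory,
"." for missing.  Coordinates in all outputs are transcript-space, 1-based;
the stop codon occupies the last three CDS positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SubstitutionCall:
    """A substitution parsed from VCF: ID carries ``<transcript>:<offset>``
    with offset 1..3 inside the stop codon (CHROM/POS are ignored -- genome
    to transcript liftover happens upstream)."""

    transcript_id: str
    position: int  # 1..3 within the stop codon
    ref: str
    alt: str


def read_substitution_vcf(path: str | Path) -> list[SubstitutionCall]:
    """Minimal VCF reader for substitution input only.

    Multi-allelic records are split; non-SNV alleles are rejected.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.id is None or ":" not in rec.id:
                raise ValueError(
                    f"VCF record at {rec.chrom}:{rec.pos} lacks an ID of the "
                    "form <transcript>:<stop-codon-offset>"
                )
            tid, off = rec.id.rsplit(":", 1)
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    raise ValueError(
                        f"{rec.id}: only single-nucleotide substitutions are "
                        "supported in VCF input"
                    )
                out.append(SubstitutionCall(tid, int(off), rec.ref.upper(), alt.upper()))
    return out


def write_scores_tsv(ids, scores, path: str | Path) -> None:
    pd.DataFrame({"variant_id": ids, "score": np.asarray(scores, dtype=float)}).to_csv(
        path, sep="\t", index=False, na_rep="."
    )


def read_scores_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=".")
    return df.set_index("variant_id")["score"]


def write_labels_tsv(ids, labels, af_proxy, path: str | Path) -> None:
    pd.DataFrame(
        {"variant_id": ids, "label": np.asarray(labels, dtype=int),
         "af_proxy": np.asarray(af_proxy, dtype=float)}
    ).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("variant_id")


def write_manifest(path: str | Path, command: str, params: dict, seed: int | None) -> None:
    """Echo the run configuration next to each output (reproducibility)."""
    manifest = {"command": command, "seed": seed, "params": params}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
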