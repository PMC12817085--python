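"""Cohort-level characterization and group-comparison statistics.

Transcriptome-style summaries: the transition table from original to
downstream stop-codon usage, the usage-weighted fraction of substitutions
that are stop-retained, the analytic expected scan length under an iid base
model, and per-frame extension-length summaries.  Group comparisons between
benign- and pathogenic-labeled variants use the Mann-Whitney U test for
continuous features, Fisher's exact test for binary ones, with
Benjamini-Hochberg adjustment across the tested family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .extension import frameshift_extension, scan_for_stop
from .transcripts import STOP_CODONS, Transcript
from .variants import enumerate_snvs, stop_retained_counts


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionTable:
    """Counts of original stop codon vs first downstream in-frame stop codon."""

    counts: pd.DataFrame  # rows: TAA/TAG/TGA; columns: TAA/TAG/TGA/none

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts / self.counts.values.sum()

    @property
    def none_fraction(self) -> float:
        """Fraction of transcripts with no downstream in-frame stop (NSD-prone)."""
        return float(self.counts["none"].sum() / self.counts.values.sum())


def transition_table(transcripts: list[Transcript]) -> TransitionTable:
    """Tally original vs frame-0 downstream stop-codon usage per transcript."""
    if not transcripts:
        raise StatsError("need at least one transcript")
    cols = list(STOP_CODONS) + ["none"]
    counts = pd.DataFrame(0, index=list(STOP_CODONS), columns=cols)
    for t in transcripts:
        idx = scan_for_stop(t.utr3)
        downstream = "none" if idx is None else t.utr3[3 * idx : 3 * idx + 3]
        counts.loc[t.stop_codon, downstream] += 1
    return TransitionTable(counts)


def weighted_stop_retained_fraction(usage_weights: dict[str, float]) -> float:
    """Percent of stop-codon substitutions that are stop-retained, weighted
    by cohort stop-codon usage.

    Per-codon stop-retained counts come from live enumeration of the nine
    substitutions (2 of 9 for TAA, 1 of 9 for TAG and TGA), weighted by the
    supplied usage fractions over {TAA, TAG, TGA}.
    """
    if set(usage_weights) != set(STOP_CODONS):
        raise StatsError(f"weights must cover exactly {STOP_CODONS}")
    total = sum(usage_weights.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise StatsError(f"usage weights must sum to 1, got {total}")
    retained = stop_retained_counts()
    return 100.0 * sum(usage_weights[c] * retained[c] for c in STOP_CODONS) / 9.0


def expected_scan_length(nt_freqs: dict[str, float]) -> float:
    """Expected number of codons scanned until (and including) the first stop,
    under iid bases.

    With per-codon stop probability p = P(TAA) + P(TAG) + P(TGA), the scan
    length is geometric with mean 1/p; at uniform base frequencies this is
    64/3 ~= 21.3 codons.  Returns ``inf`` when p = 0 (NSD certain).
    """
    if set(nt_freqs) != set("ACGT"):
        raise StatsError("frequencies must cover exactly A, C, G, T")
    if any(f < 0 for f in nt_freqs.values()):
        raise StatsError("frequencies must be non-negative")
    if not math.isclose(sum(nt_freqs.values()), 1.0, abs_tol=1e-9):
        raise StatsError("frequencies must sum to 1")
    p_stop = sum(
        nt_freqs[c[0]] * nt_freqs[c[1]] * nt_freqs[c[2]] for c in STOP_CODONS
    )
    if p_stop == 0:
        return math.inf
    return 1.0 / p_stop


def extension_length_summary(
    transcripts: list[Transcript], frame: int = 0
) -> dict:
    """Per-transcript scan lengths in the given frame, summarized.

    Transcripts without an in-frame downstream stop (NSD) are excluded from
    the median/mean and reported as a count.  Returns a dict with keys
    ``median``, ``mean``, ``n``, ``n_nsd`` and ``histogram`` (a value_counts
    Series over lengths).
    """
    if not transcripts:
        raise StatsError("need at least one transcript")
    if frame not in (0, 1, -1):
        raise StatsError("frame must be 0, +1 or -1")
    lengths = []
    n_nsd = 0
    for t in transcripts:
        if frame == 0:
            idx = scan_for_stop(t.utr3)
            if idx is None:
                n_nsd += 1
            else:
                lengths.append(idx)
        else:
            ext = frameshift_extension(t, frame)
            if ext.nsd:
                n_nsd += 1
            else:
                lengths.append(ext.ext_len_codons)
    if not lengths:
        return {"median": None, "mean": None, "n": 0, "n_nsd": n_nsd,
                "histogram": pd.Series(dtype=int)}
    arr = np.asarray(lengths)
    return {
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "n": len(arr),
        "n_nsd": n_nsd,
        "histogram": pd.Series(arr).value_counts().sort_index(),
    }


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("x and y must have equal lengths")
    if len(x) < 3:
        raise StatsError("need at least 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_compare(
    feature_table: pd.DataFrame,
    labels,
    binary_features: tuple[str, ...] = ("idp_flag",),
) -> pd.DataFrame:
    """Compare every feature between the two label groups.

    Continuous features use the two-sided Mann-Whitney U test, binary
    features Fisher's exact test on the 2x2 contingency table; raw p-values
    are Benjamini-Hochberg adjusted across the whole family.  ``direction``
    is "higher_in_1" / "higher_in_0" by group means (binary: by rate).

    Returns one row per feature: statistic, p_raw, p_adj, direction.
    """
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise StatsError("labels must define exactly two groups")
    g0 = feature_table[y == groups[0]]
    g1 = feature_table[y == groups[1]]
    rows = []
    for col in feature_table.columns:
        a = g0[col].dropna().to_numpy()
        b = g1[col].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        if col in binary_features:
            table = [
                [int((b == 1).sum()), int((b == 0).sum())],
                [int((a == 1).sum()), int((a == 0).sum())],
            ]
            stat, p = stats.fisher_exact(table)
            higher1 = (b == 1).mean() > (a == 1).mean()
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            higher1 = b.mean() > a.mean()
        rows.append(
            {
                "feature": col,
                "statistic": float(stat),
                "p_raw": float(p),
                "direction": "higher_in_1" if higher1 else "higher_in_0",
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out[["feature", "statistic", "p_raw", "p_adj", "direction"]]
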