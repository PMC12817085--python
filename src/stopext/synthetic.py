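"""Seeded generators for transcripts and labeled variant cohorts.

Every stage of the pipeline is testable without downloads: the generator
emulates transcript sets (stop-codon usage at the human transcriptome
proportions, log-normal 3'UTR lengths, beta-distributed per-transcript GC)
and labeled cohorts in which pathogenic-labeled variants carry longer, more
hydrophobic, more aggregation-prone C-terminal extensions on GC-richer,
longer 3'UTRs -- the direction of every planted contrast is recorded in
:data:`EXPECTED_SIGNS` and asserted by the test suite.

The generator plants *distributional* structure only; it does not emulate
population genetics (drift, selection) or the score distributions of real
annotation tools, whose stand-ins here are simple shifted Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .extension import ExtensionResult, extension_for_variant
from .features import AnnotationRecord, KD_SCALE, assemble_features, feature_frame
from .transcripts import GENETIC_CODE, Transcript, validate
from .variants import StopVariant, enumerate_snvs

#: Human-transcriptome stop-codon usage used as the generator default.
STOP_USAGE = {"TGA": 0.492, "TAA": 0.284, "TAG": 0.224}

#: Residues enriched in pathogenic vs benign extensions (hydrophobic/rigid
#: vs hydrophilic/flexible).
PATHOGENIC_RESIDUES = "LPAC"
BENIGN_RESIDUES = "SKEY"

#: Planted direction of each feature: +1 means higher in pathogenic-labeled
#: rows, -1 higher in benign-labeled rows.
EXPECTED_SIGNS: dict[str, int] = {
    "CADD": +1, "GERP": +1, "PhyloP100": +1, "PhastCons100": +1,
    "utr3_length": +1, "utr3_gc": +1, "mrna_stability_z": +1,
    "pLI": +1, "LOEUF": -1, "s_het": +1,
    "ext_length": +1, "kd_mean": +1, "mj_mean": +1,
    "tango_max": +1, "canya": +1, "idp_flag": +1,
}

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_CODONS_FOR: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    _CODONS_FOR.setdefault(GENETIC_CODE[_c], []).append(_c)


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters: study conditions first, effect sizes second.

    Cohort sizes default to the scale of real curated stop-loss cohorts
    (about 620 training variants at a 1:1 class ratio; an imbalanced test
    configuration of 187 pathogenic vs 371 benign is available through
    :meth:`test_set`).  Effect sizes plant the observed contrasts: a 2.2x
    longer extension, a Dirichlet-style tilt of extension residues toward
    L/P/A/C (away from S/K/E/Y), GC-richer and longer 3'UTRs, shifted
    annotation-score proxies, and IDP rates of 10.0% vs 1.3%.
    """

    seed: int = 0
    n_transcripts: int = 200
    n_variants: int = 620
    pathogenic_fraction: float = 0.5
    # transcript geometry
    cds_codons_mu: float = 5.8          # lognormal of protein length, ~330 aa median
    cds_codons_sigma: float = 0.5
    utr_len_mu: float = 6.3             # lognormal of 3'UTR tail length, ~545 nt median
    utr_len_sigma: float = 0.7
    gc_alpha: float = 9.0               # beta prior of per-transcript GC (~0.45)
    gc_beta: float = 11.0
    stop_usage: tuple[tuple[str, float], ...] = tuple(STOP_USAGE.items())
    # planted effect sizes (set to the "null" values for a no-signal cohort)
    ext_len_median: float = 12.0        # benign median extension, codons
    ext_len_sigma: float = 0.8
    ext_len_multiplier: float = 2.2     # pathogenic/benign extension-length ratio
    aa_tilt: float = 3.0                # relative weight of enriched residues
    gc_shift: float = 0.10              # extra GC for pathogenic 3'UTR tails
    synonym_gc_pref: float = 1.0        # GC tilt of pathogenic synonymous codons
    utr_len_multiplier: float = 1.6     # pathogenic/benign UTR tail-length ratio
    score_shift: float = 1.2            # mean offset of V1-V4 proxies (SD units)
    stability_shift: float = 0.5        # mRNA-stability Z offset
    constraint_shift: float = 0.6       # pLI/LOEUF/s_het offset (log or logit scale)
    idp_rate_pathogenic: float = 0.100
    idp_rate_benign: float = 0.013
    af_split: bool = True               # pathogenic rows get rarer AF proxies
    missing_rate: float = 0.05          # per-cell missingness of annotations

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "CohortSpec":
        """A zero-effect cohort: both labels drawn from the benign baseline."""
        return cls(
            seed=seed,
            ext_len_multiplier=1.0,
            aa_tilt=0.0,
            gc_shift=0.0,
            synonym_gc_pref=0.0,
            utr_len_multiplier=1.0,
            score_shift=0.0,
            stability_shift=0.0,
            constraint_shift=0.0,
            idp_rate_pathogenic=0.013,
            af_split=False,
            **kw,
        )

    def test_set(self, seed: int | None = None) -> "CohortSpec":
        """The imbalanced evaluation configuration (187 P/LP vs 371 B/LB)."""
        return replace(
            self,
            seed=self.seed + 1 if seed is None else seed,
            n_variants=558,
            pathogenic_fraction=187 / 558,
        )


@dataclass(frozen=True)
class LabeledCohort:
    """A generated cohort: feature matrix, labels, AF proxy, and provenance."""

    features: pd.DataFrame
    labels: np.ndarray
    af_proxy: np.ndarray
    transcripts: list[Transcript] = field(compare=False, default_factory=list)
    variants: list[StopVariant] = field(compare=False, default_factory=list)
    extensions: list[ExtensionResult] = field(compare=False, default_factory=list)

    def __iter__(self) -> Iterator:
        return iter((self.features, self.labels, self.af_proxy))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    """n bases with exact GC count round(gc*n), shuffled (G/C and A/T 50:50)."""
    n_gc = int(round(gc * n))
    bases = list(
        rng.choice(list("GC"), size=n_gc).tolist()
        + rng.choice(list("AT"), size=n - n_gc).tolist()
    )
    rng.shuffle(bases)
    return "".join(bases)


def _random_cds(rng: np.random.Generator, n_codons: int, stop: str) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons)
    return "".join(codons) + stop


def _sample_stop(rng: np.random.Generator, usage: dict[str, float]) -> str:
    stops = list(usage)
    w = np.array([usage[s] for s in stops], dtype=float)
    return str(rng.choice(stops, p=w / w.sum()))


def gen_transcripts(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[Transcript]:
    """Generate ``spec.n_transcripts`` valid transcripts.

    Stop codons are sampled at the human usage proportions (TGA predominant);
    CDS codons are uniform sense codons (no internal in-frame stop by
    construction); the 3'UTR is iid with an exact per-transcript GC target
    drawn from the beta prior.
    """
    rng = rng or np.random.default_rng(spec.seed)
    usage = dict(spec.stop_usage)
    out = []
    for i in range(spec.n_transcripts):
        n_codons = max(10, int(rng.lognormal(spec.cds_codons_mu, spec.cds_codons_sigma)))
        utr_len = max(30, int(rng.lognormal(spec.utr_len_mu, spec.utr_len_sigma)))
        gc = float(rng.beta(spec.gc_alpha, spec.gc_beta))
        t = Transcript(
            id=f"SYN{i:05d}",
            cds=_random_cds(rng, n_codons, _sample_stop(rng, usage)),
            utr3=_random_bases(rng, utr_len, gc),
        )
        out.append(validate(t))
    return out


def _tilted_aa_probs(tilt: float, favor: str) -> np.ndarray:
    """Probabilities over the 20 residues with ``favor`` up-weighted by tilt."""
    from .features import AMINO_ACIDS

    w = np.ones(len(AMINO_ACIDS))
    for i, a in enumerate(AMINO_ACIDS):
        if a in favor:
            w[i] += tilt
    return w / w.sum()


def _back_translate(rng: np.random.Generator, peptide: str, gc_pref: float) -> str:
    """Pick a synonymous codon per residue, weighting GC-rich synonyms by
    (1 + gc_pref) per G/C base."""
    parts = []
    for aa in peptide:
        codons = _CODONS_FOR[aa]
        w = np.array([(1.0 + gc_pref) ** (c.count("G") + c.count("C")) for c in codons])
        parts.append(str(rng.choice(codons, p=w / w.sum())))
    return "".join(parts)


def _planted_utr(
    rng: np.random.Generator, spec: CohortSpec, pathogenic: bool
) -> tuple[str, int]:
    """Construct a 3'UTR carrying a planted in-frame extension.

    Returns the UTR and the planted extension length (codons before the
    downstream stop).  The extension is back-translated from a tilted
    residue distribution, followed by a usage-sampled stop codon and a
    random tail.
    """
    from .features import AMINO_ACIDS

    median = spec.ext_len_median * (spec.ext_len_multiplier if pathogenic else 1.0)
    ext_len = int(round(rng.lognormal(np.log(median), spec.ext_len_sigma)))
    ext_len = max(1, ext_len)
    favor = PATHOGENIC_RESIDUES if pathogenic else BENIGN_RESIDUES
    probs = _tilted_aa_probs(spec.aa_tilt, favor)
    peptide = "".join(rng.choice(list(AMINO_ACIDS), size=ext_len, p=probs))
    gc = float(rng.beta(spec.gc_alpha, spec.gc_beta)) + (spec.gc_shift if pathogenic else 0.0)
    gc = min(max(gc, 0.05), 0.9)
    tail_len = max(
        30,
        int(
            rng.lognormal(spec.utr_len_mu, spec.utr_len_sigma)
            * (spec.utr_len_multiplier if pathogenic else 1.0)
        ),
    )
    utr = (
        _back_translate(rng, peptide, gc_pref=spec.synonym_gc_pref if pathogenic else 0.0)
        + _sample_stop(rng, dict(spec.stop_usage))
        + _random_bases(rng, tail_len, gc)
    )
    return utr, ext_len


def _annotation(
    rng: np.random.Generator, spec: CohortSpec, pathogenic: bool, kd_mean: float
) -> AnnotationRecord:
    s = spec.score_shift if pathogenic else 0.0
    loeuf = float(np.exp(rng.normal(0.0 - (spec.constraint_shift if pathogenic else 0.0), 0.4)))
    s_het = float(np.exp(rng.normal(-4.0 + (spec.constraint_shift if pathogenic else 0.0), 0.8)))
    pli_a, pli_b = (2.0, 0.8) if (pathogenic and spec.constraint_shift > 0) else (0.8, 2.0)
    idp_rate = spec.idp_rate_pathogenic if pathogenic else spec.idp_rate_benign
    # aggregation proxies ride on hydrophobicity plus noise
    tango = float(np.clip(50 + 12 * kd_mean + rng.normal(0, 10), 0, 100))
    canya = float(np.clip(0.5 + 0.08 * kd_mean + rng.normal(0, 0.1), 0, 1))
    rec = AnnotationRecord(
        cadd=float(rng.normal(0 + s, 1)),
        gerp=float(rng.normal(0 + s, 1)),
        phylop100=float(rng.normal(0 + s, 1)),
        phastcons100=float(rng.normal(0 + s, 1)),
        mrna_stability_z=float(rng.normal((spec.stability_shift if pathogenic else 0.0), 1)),
        pli=float(rng.beta(pli_a, pli_b)),
        loeuf=loeuf,
        s_het=s_het,
        tango_max=tango,
        canya=canya,
        idp_flag=int(rng.random() < idp_rate),
    )
    if spec.missing_rate > 0:
        drop = {
            f: None
            for f in ("cadd", "gerp", "phylop100", "phastcons100",
                      "mrna_stability_z", "pli", "loeuf", "s_het",
                      "tango_max", "canya")
            if rng.random() < spec.missing_rate
        }
        if drop:
            rec = replace(rec, **drop)
    return rec


def gen_labeled_cohort(
    spec: CohortSpec, transcripts: list[Transcript] | None = None
) -> LabeledCohort:
    """Generate a labeled variant cohort with the planted contrast structure.

    Each row is a real stop-loss substitution on a generated transcript whose
    3'UTR carries a planted extension; features are assembled through the
    production feature pipeline, so every invariant of the real path holds.
    ``transcripts`` optionally supplies CDS backbones (their UTRs are
    replaced by the planted construction).
    """
    rng = np.random.default_rng([spec.seed, 2])
    base = transcripts or gen_transcripts(
        replace(spec, n_transcripts=min(spec.n_transcripts, spec.n_variants)),
        np.random.default_rng([spec.seed, 1]),
    )
    n_path = int(round(spec.n_variants * spec.pathogenic_fraction))
    labels = np.array([1] * n_path + [0] * (spec.n_variants - n_path))
    rng.shuffle(labels)

    rows, ids, afs = [], [], []
    out_transcripts, out_variants, out_exts = [], [], []
    for i, y in enumerate(labels):
        backbone = base[int(rng.integers(len(base)))]
        utr, _ = _planted_utr(rng, spec, bool(y))
        t = Transcript(id=f"VAR{i:05d}", cds=backbone.cds, utr3=utr,
                       gene_id=backbone.id)
        losses = [v for v in enumerate_snvs(t) if v.consequence == "stop_loss"]
        v = losses[int(rng.integers(len(losses)))]
        ext = extension_for_variant(t, v)
        kd = float(np.mean([KD_SCALE[a] for a in ext.peptide])) if ext.peptide else 0.0
        ann = _annotation(rng, spec, bool(y), kd)
        rows.append(assemble_features(t, v, ext, ann))
        ids.append(f"{t.id}:{v.hgvs_c.split(':')[-1]}")
        if spec.af_split:
            af = 10 ** -rng.uniform(4.0, 6.0) if y else 10 ** -rng.uniform(1.5, 3.0)
        else:
            af = 10 ** -rng.uniform(1.5, 6.0)
        afs.append(af)
        out_transcripts.append(t)
        out_variants.append(v)
        out_exts.append(ext)

    return LabeledCohort(
        features=feature_frame(rows, index=ids),
        labels=labels,
        af_proxy=np.array(afs),
        transcripts=out_transcripts,
        variants=out_variants,
        extensions=out_exts,
    )
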