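"""Score calibration: two-component Gaussian mixture and LR thresholds.

Pathogenicity scores over a large variant set form a bimodal distribution
whose two Gaussian components are identified with the benign/likely-benign
(B/LB) and pathogenic/likely-pathogenic (P/LP) populations.  The likelihood
ratio LR(x) = P(x | P/LP) / P(x | B/LB) is the ratio of the two component
*densities* (no mixing weights, matching the defining formula); score
cutoffs solve LR(x) = 9 and LR(x) = 1/9, i.e. 90% likelihood of the
respective class.  The operational cutoffs published for the full
transcriptome-wide score distribution are shipped separately as
:data:`DEFAULT_THRESHOLDS` (0.30 / 0.70), since re-deriving them
requires that external score set.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class GaussianComponent:
    mu: float
    sigma2: float
    weight: float
    label: str  # "B/LB" or "P/LP"

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise CalibrationError("component variance must be positive")


@dataclass(frozen=True)
class MixtureFit:
    """A two-component fit with the higher-mean component labeled P/LP."""

    benign: GaussianComponent
    pathogenic: GaussianComponent
    log_likelihood: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        assert self.pathogenic.mu >= self.benign.mu
        assert abs(self.benign.weight + self.pathogenic.weight - 1.0) < 1e-9


@dataclass(frozen=True)
class Thresholds:
    """Score cutoffs: ``lower`` solves LR = 1/ratio, ``upper`` LR = ratio."""

    lower: float
    upper: float
    ratio: float = 9.0

    def __post_init__(self) -> None:
        # lower == upper only in the degenerate ratio == 1 case
        if self.lower > self.upper:
            raise CalibrationError("lower threshold must not exceed upper")


#: Operational cutoffs published for the transcriptome-wide score set.
DEFAULT_THRESHOLDS = Thresholds(lower=0.30, upper=0.70)


def fit_mixture(scores, seed: int = 0) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to a score sample.

    Initialization is k-means with 10 restarts, keeping the best
    log-likelihood; fully deterministic given ``seed``.  Components are
    labeled by mean order (larger mean -> P/LP).
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise CalibrationError("need at least 10 scores to fit a mixture")
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate data: all scores identical")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        random_state=seed,
    ).fit(x)
    mus = gm.means_.ravel()
    sig2 = gm.covariances_.reshape(-1)
    w = gm.weights_.ravel()
    lo, hi = int(np.argmin(mus)), int(np.argmax(mus))
    return MixtureFit(
        benign=GaussianComponent(float(mus[lo]), float(sig2[lo]), float(w[lo]), "B/LB"),
        pathogenic=GaussianComponent(float(mus[hi]), float(sig2[hi]), float(w[hi]), "P/LP"),
        log_likelihood=float(gm.score(x) * len(x)),
        n=len(x),
        seed=seed,
    )


def likelihood_ratio(x, fit: MixtureFit):
    """LR(x) = component density of P/LP over component density of B/LB.

    Mixing weights are deliberately omitted: the defining formula is a ratio
    of the two class-conditional normal PDFs.  (A weighted posterior-odds
    variant is available via :func:`posterior_odds`.)
    """
    p = norm.pdf(x, fit.pathogenic.mu, math.sqrt(fit.pathogenic.sigma2))
    b = norm.pdf(x, fit.benign.mu, math.sqrt(fit.benign.sigma2))
    return p / b


def posterior_odds(x, fit: MixtureFit):
    """Weighted variant of the ratio: mixture-posterior odds of P/LP vs B/LB."""
    return likelihood_ratio(x, fit) * (fit.pathogenic.weight / fit.benign.weight)


def _log_lr(x: float, fit: MixtureFit) -> float:
    sp, sb = fit.pathogenic.sigma2, fit.benign.sigma2
    mp, mb = fit.pathogenic.mu, fit.benign.mu
    return (
        -0.5 * math.log(sp / sb)
        - (x - mp) ** 2 / (2 * sp)
        + (x - mb) ** 2 / (2 * sb)
    )


def _solve_one(fit: MixtureFit, target_log_lr: float) -> float:
    """Solve log LR(x) = target for the root strictly between the means."""
    mb, mp = fit.benign.mu, fit.pathogenic.mu
    sb, sp = fit.benign.sigma2, fit.pathogenic.sigma2
    if math.isclose(sb, sp, rel_tol=1e-12, abs_tol=1e-15):
        # equal variances: log LR is linear in x
        return (mb + mp) / 2 + sb * target_log_lr / (mp - mb)
    # unequal variances: quadratic a x^2 + b x + c = target-adjusted 0
    a = 0.5 * (1 / sb - 1 / sp)
    b = mp / sp - mb / sb
    c = mb**2 / (2 * sb) - mp**2 / (2 * sp) - 0.5 * math.log(sp / sb) - target_log_lr
    disc = b * b - 4 * a * c
    if disc < 0:
        raise CalibrationError(
            f"no real solution of LR(x)=exp({target_log_lr:.4f}) "
            f"(means {mb:.4f}/{mp:.4f}, variances {sb:.3g}/{sp:.3g})"
        )
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (+1, -1)]
    inside = [r for r in roots if mb < r < mp]
    if not inside:
        raise CalibrationError(
            f"no root strictly between the component means {mb:.4f} and {mp:.4f}; "
            f"candidate roots {roots}"
        )
    # polish the selected root numerically
    r = min(inside, key=lambda r: abs(r - (mb + mp) / 2))
    f = lambda x: _log_lr(x, fit) - target_log_lr
    eps = 1e-9 * max(1.0, mp - mb)
    lo, hi = mb + eps, mp - eps
    if f(lo) * f(hi) < 0:
        return float(brentq(f, lo, hi, xtol=1e-14))
    return float(r)


def solve_thresholds(fit: MixtureFit, ratio: float = 9.0) -> Thresholds:
    """Solve LR(x) = ratio (upper cutoff) and LR(x) = 1/ratio (lower cutoff).

    With equal component variances the solution is the closed form
    x = (mu_B + mu_P)/2 + sigma^2 ln(ratio) / (mu_P - mu_B); otherwise the
    quadratic in x is solved and the root strictly between the component
    means selected.
    """
    if ratio < 1:
        raise CalibrationError("ratio must be >= 1")
    upper = _solve_one(fit, math.log(ratio))
    lower = _solve_one(fit, -math.log(ratio))
    return Thresholds(lower=lower, upper=upper, ratio=ratio)


def classify_score(score: float, thresholds: Thresholds) -> str:
    """Three-bin call: >= upper -> potentially P/LP, <= lower -> potentially B/LB.

    Boundaries are inclusive toward the decisive bins.
    """
    if score >= thresholds.upper:
        return "potentially_PLP"
    if score <= thresholds.lower:
        return "potentially_BLB"
    return "uncertain"


def calibration_report(fit: MixtureFit, thresholds: Thresholds) -> str:
    """JSON report with component parameters, solved cutoffs, ratio, n, seed."""
    return json.dumps(
        {
            "components": {
                "B/LB": asdict(fit.benign),
                "P/LP": asdict(fit.pathogenic),
            },
            "log_likelihood": fit.log_likelihood,
            "n": fit.n,
            "seed": fit.seed,
            "thresholds": asdict(thresholds),
        },
        indent=2,
    )
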