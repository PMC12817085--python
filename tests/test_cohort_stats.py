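import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stopext as se
from stopext.cohort_stats import StatsError

HUMAN_USAGE = {"TGA": 0.492, "TAA": 0.284, "TAG": 0.224}


def transcript(stop="TGA", utr3="TTTTAA", tid="t"):
    return se.validate(se.Transcript(id=tid, cds="ATG" + stop, utr3=utr3))


class TestTransitionTable:
    def test_single_transcript_immediate_stop(self):
        tt = se.transition_table([transcript(utr3="TAACCC")])
        assert tt.counts.loc["TGA", "TAA"] == 1
        assert tt.fractions.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gc_only_utrs_are_all_none(self):
        ts = [transcript(utr3="GCGCGCGCG", tid=f"t{i}") for i in range(5)]
        tt = se.transition_table(ts)
        assert tt.none_fraction == 1.0

    def test_none_fraction_matches_geometric_survival(self):
        """At uniform bases the per-codon stop chance is 3/64; surviving k
        codons has probability (61/64)^k."""
        rng = np.random.default_rng(5)
        k = 33  # complete codons in a 100-nt UTR scan... use 99-nt UTRs
        ts = [transcript(utr3="".join(rng.choice(list("ACGT"), size=99)),
                         tid=f"t{i}") for i in range(2000)]
        tt = se.transition_table(ts)
        expected = (61 / 64) ** 33
        se_mc = math.sqrt(expected * (1 - expected) / 2000)
        assert abs(tt.none_fraction - expected) < 4 * se_mc + 1e-9


class TestWeightedStopRetained:
    def test_printed_usage_weights_give_14_3_percent(self):
        pct = se.weighted_stop_retained_fraction(HUMAN_USAGE)
        assert round(pct, 1) == 14.3

    def test_pure_taa_cohort(self):
        pct = se.weighted_stop_retained_fraction({"TAA": 1.0, "TAG": 0.0, "TGA": 0.0})
        assert pct == pytest.approx(100 * 2 / 9)

    def test_complement_is_stop_loss_fraction(self):
        pct = se.weighted_stop_retained_fraction(HUMAN_USAGE)
        assert pct + (100 - pct) == 100.0
        assert round(100 - pct, 1) == 85.7

    def test_invalid_weights_rejected(self):
        with pytest.raises(StatsError):
            se.weighted_stop_retained_fraction({"TAA": 0.5, "TAG": 0.2, "TGA": 0.2})


class TestExpectedScanLength:
    def test_uniform_bases_give_64_thirds(self):
        e = se.expected_scan_length({b: 0.25 for b in "ACGT"})
        assert e == pytest.approx(64 / 3)
        assert round(e, 1) == 21.3

    def test_stop_free_composition_is_nsd_certain(self):
        assert se.expected_scan_length(
            {"T": 1.0, "A": 0.0, "C": 0.0, "G": 0.0}) == math.inf

    def test_matches_monte_carlo_simulation(self):
        rng = np.random.default_rng(17)
        n = 20_000
        # geometric scan: codons until first success at p = 3/64
        draws = rng.geometric(3 / 64, size=n)
        e = se.expected_scan_length({b: 0.25 for b in "ACGT"})
        assert abs(draws.mean() - e) / e < 0.02


class TestExtensionLengthSummary:
    def test_all_nsd_cohort_is_empty_with_count(self):
        ts = [transcript(utr3="GGGGGG", tid=f"t{i}") for i in range(3)]
        s = se.extension_length_summary(ts)
        assert s["median"] is None and s["n"] == 0 and s["n_nsd"] == 3

    def test_iid_uniform_mean_near_analytic(self):
        rng = np.random.default_rng(23)
        ts = [transcript(utr3="".join(rng.choice(list("ACGT"), size=900)),
                         tid=f"t{i}") for i in range(1500)]
        for frame in (0, 1, -1):
            s = se.extension_length_summary(ts, frame)
            # scan length counts the stop codon; ext length excludes it
            assert s["mean"] + 1 == pytest.approx(64 / 3, rel=0.05)

    def test_histogram_counts_match_n(self):
        ts = [transcript(utr3="TAACCC", tid="a"), transcript(utr3="AAATAG", tid="b")]
        s = se.extension_length_summary(ts)
        assert int(s["histogram"].sum()) == s["n"] == 2


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert se.spearman(x, x)[0] == pytest.approx(1.0)
        assert se.spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_computation(self):
        x = [3.1, 1.2, 5.5, 2.2, 4.4, 0.1, 2.2, 9.0, 7.7, 6.6]
        y = [0.5, 2.5, 1.5, 3.5, 2.0, 8.0, 2.0, 0.2, 5.0, 1.0]
        rx, ry = sps.rankdata(x), sps.rankdata(y)  # average ranks for ties
        expected = np.corrcoef(rx, ry)[0, 1]       # Pearson of the ranks
        assert se.spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            se.spearman([1, 2, 3], [1, 2])


def brute_force_mannwhitney_u(a, b) -> float:
    """All-pairs count: U = #{(i,j): a_i > b_j} + 0.5 #{ties}."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def bh_by_hand(pvals):
    """Step-up: p_(i) * m / i, cumulative minimum from the largest rank."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestGroupCompare:
    def test_mannwhitney_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(31)
        a = rng.integers(0, 10, size=12).astype(float)
        b = rng.integers(0, 10, size=8).astype(float)
        u, _ = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert u == brute_force_mannwhitney_u(a, b)

    def test_bh_step_up_matches_hand_formula(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        p2 = np.array([0.001, 0.02, 0.8, 0.04, 0.3])
        np.testing.assert_allclose(
            multipletests(p2, method="fdr_bh")[1], bh_by_hand(p2))

    def test_identical_groups_are_nonsignificant(self):
        X = pd.DataFrame({"f": list(range(10)) * 2})
        y = [0] * 10 + [1] * 10
        out = se.group_compare(X, y, binary_features=())
        assert (out["p_adj"] >= 0.99).all()

    def test_planted_shift_is_flagged(self, default_cohort):
        out = se.group_compare(
            default_cohort.features[["kd_mean", "ext_length", "idp_flag"]],
            default_cohort.labels,
        )
        kd = out.set_index("feature").loc["kd_mean"]
        assert kd["p_adj"] < 0.05 and kd["direction"] == "higher_in_1"
        idp = out.set_index("feature").loc["idp_flag"]
        assert idp["direction"] == "higher_in_1"

    def test_adjusted_p_never_below_raw(self, default_cohort):
        out = se.group_compare(default_cohort.features, default_cohort.labels)
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_single_group_rejected(self):
        with pytest.raises(StatsError):
            se.group_compare(pd.DataFrame({"f": [1.0, 2.0]}), [0, 0])
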