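"""Per-transcript tail statistics: prefilter, summaries, Welch test, densities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_records
from tailprofiler import synthdata
from tailprofiler.tailprofile import (
    DEFAULT_WINDOWS,
    WINDOW_150NT,
    WINDOW_60NT,
    TailWindow,
    differential_mean_tail,
    prefilter_transcripts,
    summarize_tails,
    tail_length_density,
    window_fraction_change,
)


def records_from_counts(counts):
    """counts: {transcript: {condition: (n_rep1, n_rep2, ...)}} -> records frame."""
    rows = []
    for tx, conds in counts.items():
        for cond, reps in conds.items():
            for r, n in enumerate(reps, start=1):
                rows += [(tx, 100.0, cond, r)] * n
    return make_records(rows)


class TestPrefilter:
    def test_kept_when_one_condition_qualifies(self):
        recs = records_from_counts({"tx": {"A": (12, 11, 0), "B": (0, 0, 0)}})
        assert prefilter_transcripts(recs) == ["tx"]

    def test_excluded_when_no_condition_has_two_deep_replicates(self):
        recs = records_from_counts({"tx": {"A": (12, 9, 9), "B": (9, 9, 9)}})
        assert prefilter_transcripts(recs) == []

    def test_six_transcript_fixture_matches_rule_oracle(self):
        counts = {
            "t1": {"A": (12, 11, 0), "B": (0, 0, 0)},   # kept
            "t2": {"A": (12, 9, 9), "B": (9, 9, 9)},    # excluded
            "t3": {"A": (10, 10, 10), "B": (1, 1, 1)},  # kept
            "t4": {"A": (9, 9, 9), "B": (9, 9, 10)},    # excluded
            "t5": {"A": (0, 0, 0), "B": (50, 50, 0)},   # kept
            "t6": {"A": (10, 0, 0), "B": (0, 10, 0)},   # excluded
        }
        # independent brute-force evaluation of the stated rule
        expected = sorted(
            tx
            for tx, conds in counts.items()
            if any(sum(n >= 10 for n in reps) >= 2 for reps in conds.values())
        )
        assert expected == ["t1", "t3", "t5"]
        assert prefilter_transcripts(records_from_counts(counts)) == expected

    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=1, max_value=3))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_thresholds(self, min_reads, min_replicates):
        recs = records_from_counts(
            {
                "t1": {"A": (12, 11, 0)},
                "t2": {"A": (5, 5, 5), "B": (15, 2, 2)},
                "t3": {"A": (10, 10, 10)},
            }
        )
        base = set(prefilter_transcripts(recs, min_reads, min_replicates))
        stricter = set(prefilter_transcripts(recs, min_reads + 1, min_replicates))
        assert stricter <= base
        stricter2 = set(prefilter_transcripts(recs, min_reads, min_replicates + 1))
        assert stricter2 <= base


class TestSummaries:
    def test_window_boundaries_half_open(self):
        tails = [25, 45, 80, 119, 120, 150, 209, 210, 230]
        recs = make_records([("tx", t, "A", 1) for t in tails])
        s = summarize_tails(recs).iloc[0]
        assert s["n_reads"] == 9
        assert s["pct_~60-nt"] == pytest.approx(100 * 3 / 9)
        assert s["pct_~150-nt"] == pytest.approx(100 * 3 / 9)

    def test_single_read(self):
        recs = make_records([("tx", 150.0, "A", 1)])
        s = summarize_tails(recs).iloc[0]
        assert s["mean_tail"] == 150.0
        assert s["pct_~150-nt"] == 100.0

    def test_matches_brute_force_counting_exactly(self):
        rng = np.random.default_rng(42)
        tails = rng.uniform(0, 250, 1000)
        tx = rng.choice(["a", "b", "c"], 1000)
        recs = make_records(list(zip(tx, tails, ["A"] * 1000, [1] * 1000)))
        out = summarize_tails(recs).set_index("transcript_id")
        for t in "abc":
            sub = tails[tx == t]
            for w in DEFAULT_WINDOWS:
                expected = 100.0 * sum(w.lower <= x < w.upper for x in sub) / len(sub)
                assert out.loc[t, w.column] == expected  # exact, no tolerance

    def test_mean_invariant_to_read_order(self):
        rng = np.random.default_rng(0)
        tails = rng.uniform(10, 200, 200)
        recs = make_records([("tx", t, "A", 1) for t in tails])
        shuffled = recs.sample(frac=1, random_state=1).reset_index(drop=True)
        a = summarize_tails(recs).iloc[0]["mean_tail"]
        b = summarize_tails(shuffled).iloc[0]["mean_tail"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            summarize_tails(
                make_records([("t", 50, "A", 1)]),
                (TailWindow("a", 0, 100), TailWindow("b", 50, 150)),
            )


def summaries_from_means(means):
    """means: {condition: {transcript: [replicate means]}} -> summary frame."""
    rows = []
    for cond, txs in means.items():
        for tx, reps in txs.items():
            for r, m in enumerate(reps, 1):
                rows.append((tx, cond, r, 10, m))
    return pd.DataFrame(rows, columns=["transcript_id", "condition", "replicate", "n_reads", "mean_tail"])


class TestDifferentialMeanTail:
    def test_identical_groups_are_null(self):
        s = summaries_from_means({"A": {"t": [100, 110, 120]}, "B": {"t": [100, 110, 120]}})
        r = differential_mean_tail(s, "A", "B").iloc[0]
        assert r["delta"] == 0
        assert r["p_value"] == pytest.approx(1.0)
        assert r["class"] == "ns"

    def test_known_welch_case(self):
        # frozen from the closed-form Welch computation: equal variances 100,
        # se = sqrt(200/3), t = -40/8.165 = -4.899, df = 4, p = 0.00804
        s = summaries_from_means({"A": {"t": [140, 150, 160]}, "B": {"t": [100, 110, 120]}})
        r = differential_mean_tail(s, "A", "B").iloc[0]
        assert r["t_stat"] == pytest.approx(-4.89898, abs=1e-4)
        assert r["p_value"] == pytest.approx(0.00804, abs=1e-4)
        assert r["class"] == "-"

    def test_zero_variance_convention(self):
        s = summaries_from_means({"A": {"t": [150, 150, 150]}, "B": {"t": [60, 60, 60]}})
        r = differential_mean_tail(s, "A", "B").iloc[0]
        assert r["p_value"] == 0.0
        assert r["class"] == "-"

    def test_not_testable_with_single_replicate(self):
        s = summaries_from_means({"A": {"t": [150]}, "B": {"t": [60, 70, 80]}})
        r = differential_mean_tail(s, "A", "B").iloc[0]
        assert r["class"] == "not_testable"
        assert np.isnan(r["p_value"])

    def test_matches_reference_welch_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(100, 15, 3)
            b = rng.normal(105, 25, 3)
            s = summaries_from_means({"A": {"t": list(a)}, "B": {"t": list(b)}})
            r = differential_mean_tail(s, "A", "B").iloc[0]
            ref = sps.ttest_ind(b, a, equal_var=False)
            assert abs(r["p_value"] - ref.pvalue) < 1e-12
            assert r["t_stat"] == pytest.approx(ref.statistic, abs=1e-10)

    def test_read_level_variant(self):
        rng = np.random.default_rng(8)
        recs = make_records(
            [("t", x, "A", 1) for x in rng.normal(150, 10, 30)]
            + [("t", x, "B", 1) for x in rng.normal(60, 10, 30)]
        )
        s = summarize_tails(recs)
        r = differential_mean_tail(s, "A", "B", level="read", records=recs).iloc[0]
        assert r["class"] == "-"
        assert r["p_value"] < 1e-6


class TestWindowFractionChange:
    def test_stated_formula(self):
        s = summaries_from_means({"A": {"t": [0]}, "B": {"t": [0]}})
        s["pct_~60-nt"] = [20.0, 40.0]
        out = window_fraction_change(s, "A", "B", WINDOW_60NT)
        assert out.iloc[0]["log2fc"] == pytest.approx(np.log2(40.1 / 20.1), abs=1e-12)

    def test_equal_percent_gives_zero(self):
        s = summaries_from_means({"A": {"t": [0, 0]}, "B": {"t": [0, 0]}})
        s["pct_~60-nt"] = 33.0
        out = window_fraction_change(s, "A", "B", WINDOW_60NT)
        assert out.iloc[0]["log2fc"] == 0.0

    def test_planted_doubling_centres_near_one(self):
        # ~60-nt occupancy doubles 30% -> 60%: read counts at 300/replicate
        rng = np.random.default_rng(2)
        rows = []
        for tx in range(30):
            for cond, frac in (("A", 0.3), ("B", 0.6)):
                for rep in (1, 2, 3):
                    n = 300
                    n60 = rng.binomial(n, frac)
                    tails = np.concatenate(
                        [rng.uniform(40, 110, n60), rng.uniform(130, 200, n - n60)]
                    )
                    rows += [(f"t{tx}", t, cond, rep) for t in tails]
        s = summarize_tails(make_records(rows))
        out = window_fraction_change(s, "A", "B", WINDOW_60NT)
        assert abs(out["log2fc"].mean() - 1.0) < 0.1


class TestDensity:
    def test_single_value_occupies_one_bin(self):
        recs = make_records([("t", 100.0, "A", r) for r in (1, 2, 3) for _ in range(5)])
        prof = tail_length_density(recs)["A"]
        pct = prof.per_replicate_percent
        assert (pct.sum(axis=1) - 100).abs().max() < 1e-9
        col = pct.columns[np.digitize(100.0, np.arange(0, 351, 5)) - 1]
        assert (pct[col] == 100.0).all()

    def test_replicate_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        recs = make_records(
            [("t", x, "A", r) for r in (1, 2) for x in rng.uniform(0, 400, 500)]
        )
        prof = tail_length_density(recs)["A"]
        np.testing.assert_allclose(prof.per_replicate_percent.sum(axis=1), 100.0, atol=1e-6)

    def test_bimodal_mixture_recovers_both_modes(self):
        mix = synthdata.TailMixtureSpec(((60.0, 15.0, 0.5), (150.0, 20.0, 0.5)))
        rng = np.random.default_rng(4)
        rows = []
        for rep in (1, 2, 3):
            rows += [("t", x, "A", rep) for x in mix.sample(4000, rng)]
        prof = tail_length_density(make_records(rows))["A"]
        y = prof.smoothed
        x = prof.bin_centers
        local_max = [x[i] for i in range(1, len(y) - 1) if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] > 0.5]
        assert any(abs(m - 60) <= 10 for m in local_max)
        assert any(abs(m - 150) <= 10 for m in local_max)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            tail_length_density(make_records([("t", 10, "A", 1)]), bin_width=0)

    def test_transcript_weighting_changes_unbalanced_mixture(self):
        # 10:1 read imbalance between a short- and long-tailed transcript:
        # transcript weighting must pull the short mode's share down to ~50%
        rows = [("big", 60.0, "A", 1)] * 200 + [("small", 150.0, "A", 1)] * 20
        recs = make_records(rows)
        by_read = tail_length_density(recs, weighting="read")["A"]
        by_tx = tail_length_density(recs, weighting="transcript")["A"]
        col = by_read.per_replicate_percent.columns[12]  # bin containing 60 nt
        assert by_read.per_replicate_percent[col].iloc[0] > 85
        assert by_tx.per_replicate_percent[col].iloc[0] == pytest.approx(50.0)
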