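import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from regenchron.differential import run_adjacent_contrasts, run_baseline_contrasts
from regenchron.episodes import (
    EXACT_THRESHOLD,
    PairedCalls,
    baseline_divergence_counts,
    cumulative_first_detection,
    detect_episodes,
    mcnemar_test,
    paired_significance_counts,
    times_significant_histogram,
)
from regenchron.simulate import SimConfig, simulate_timecourse


def exact_binomial_oracle(b: int, c: int) -> float:
    """Full enumeration of the two-sided binomial(b+c, 1/2) tail."""
    n = b + c
    if n == 0 or abs(b - c) <= 1:
        return 1.0
    hi = max(b, c)
    tail = sum(Fraction(math.comb(n, i)) for i in range(hi, n + 1)) / Fraction(2) ** n
    return float(min(Fraction(1), 2 * tail))


def _series(values, name, probes=None):
    idx = probes or [f"p{i}" for i in range(len(values))]
    return pd.Series(values, index=pd.Index(idx, name="probe_id"), name=name)


class TestPairedCounts:
    def test_enumeration_example(self):
        earlier = _series(["up", "down", "ns", "ns", "up"], "0-0.5")
        later = _series(["up", "ns", "down", "up", "ns"], "0.5-1")
        paired = paired_significance_counts(earlier, later)
        assert (paired.a, paired.b, paired.c, paired.d) == (1, 2, 2, 0)
        assert paired.n == 5

    def test_identical_vectors_are_fully_concordant(self):
        calls = _series(["up", "ns", "down"], "x")
        paired = paired_significance_counts(calls, calls.rename("y"))
        assert paired.b == paired.c == 0

    def test_disjoint_sets(self):
        e = ["up"] * 3 + ["ns"] * 97
        l = ["ns"] * 3 + ["down"] * 7 + ["ns"] * 90
        paired = paired_significance_counts(_series(e, "e"), _series(l, "l"))
        assert (paired.a, paired.b, paired.c, paired.d) == (0, 3, 7, 90)

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="universe"):
            paired_significance_counts(
                _series(["up"], "e", ["p1"]), _series(["up"], "l", ["p2"])
            )


class TestMcNemar:
    def test_continuity_corrected_statistic_algebra(self):
        res = mcnemar_test(PairedCalls("e", "l", a=0, b=10, c=40, d=0))
        assert res.statistic == pytest.approx((29**2) / 50)
        assert res.statistic == pytest.approx(16.82)
        assert res.direction == "increase"
        assert res.method == "chi2_cc"

    def test_chi2_p_matches_distribution_tail(self):
        from scipy import stats

        res = mcnemar_test(PairedCalls("e", "l", a=0, b=10, c=40, d=0))
        assert res.p_value == pytest.approx(float(stats.chi2.sf(16.82, 1)), rel=1e-12)

    def test_exact_method_matches_full_enumeration(self):
        # every discordant split with b+c <= 60, to 1e-12
        for n in range(0, 61):
            for b in range(0, n + 1):
                c = n - b
                res = mcnemar_test(PairedCalls("e", "l", 0, b, c, 0), method="exact_binomial")
                assert res.p_value == pytest.approx(exact_binomial_oracle(b, c), abs=1e-12)

    def test_agrees_with_statsmodels(self):
        for b, c in [(2, 9), (0, 14), (5, 19), (30, 55), (40, 41)]:
            paired = PairedCalls("e", "l", a=3, b=b, c=c, d=100)
            mine = mcnemar_test(paired)
            table = [[3, b], [c, 100]]
            if mine.method == "exact_binomial":
                ref = sm_mcnemar(table, exact=True)
                if abs(b - c) > 1:  # our clamp rule differs only inside |b-c|<=1
                    assert mine.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)
            else:
                ref = sm_mcnemar(table, exact=False, correction=True)
                assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_balanced_discordance_clamps_to_one(self):
        res = mcnemar_test(PairedCalls("e", "l", 0, 5, 5, 0))
        assert res.p_value == 1.0
        assert res.direction == "none"
        res = mcnemar_test(PairedCalls("e", "l", 0, 0, 0, 10))
        assert res.p_value == 1.0

    def test_method_switch_at_25_discordant(self):
        assert mcnemar_test(PairedCalls("e", "l", 0, 4, 20, 0)).method == "exact_binomial"
        assert mcnemar_test(PairedCalls("e", "l", 0, 5, 20, 0)).method == "chi2_cc"
        assert EXACT_THRESHOLD == 25


def _calls_frame(columns: dict[str, list[str]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"))


class TestDetectEpisodes:
    def test_reference_schedule_has_18_comparisons_at_threshold_0028(self, flat_sim):
        _, matrix, samples, _ = flat_sim
        adj = run_adjacent_contrasts(matrix, samples)
        calls = detect_episodes(adj.calls)
        assert len(calls) == 18
        assert calls[0].n_comparisons == 18
        assert calls[0].adjusted_threshold == pytest.approx(0.05 / 18)
        assert round(calls[0].adjusted_threshold, 4) == 0.0028
        # the first adjacent contrast is only ever the earlier member
        assert calls[0].contrast_earlier == "0-0.5"
        assert all(c.contrast_later != "0-0.5" for c in calls)

    def test_recovers_injected_step_boundaries(self):
        cfg = SimConfig(
            n_probes=3000,
            archetype_mix={"step@3": 0.1, "step@20": 0.1, "step@24": 0.1, "flat": 0.7},
            seed=23,
        )
        matrix, samples, _ = simulate_timecourse(cfg)
        adj = run_adjacent_contrasts(matrix, samples)
        flagged = [c.contrast_later for c in detect_episodes(adj.calls) if c.flagged]
        assert flagged == ["2-3", "18-20", "22-24"]

    def test_decrease_mode_flags_the_interval_after_a_step(self):
        cfg = SimConfig(n_probes=3000, archetype_mix={"step@3": 0.1, "flat": 0.9}, seed=29)
        matrix, samples, _ = simulate_timecourse(cfg)
        adj = run_adjacent_contrasts(matrix, samples)
        flagged = [c.contrast_later for c in detect_episodes(adj.calls, mode="decrease") if c.flagged]
        assert flagged == ["3-4"]

    def test_flags_invariant_to_probe_order_and_direction_relabeling(self):
        rng = np.random.default_rng(0)
        cols = {}
        days = [0, 0.5, 1, 1.5, 2]
        labels = [f"{a:g}-{b:g}" for a, b in zip(days[:-1], days[1:])]
        for i, lab in enumerate(labels):
            p_sig = 0.3 if lab == "1-1.5" else 0.02
            cols[lab] = rng.choice(["up", "down", "ns"], size=400, p=[p_sig / 2, p_sig / 2, 1 - p_sig])
        frame = _calls_frame(cols)
        base = detect_episodes(frame)
        shuffled = frame.sample(frac=1, random_state=1)
        relabeled = frame.replace({"up": "down", "down": "up"})
        for variant in (shuffled, relabeled):
            alt = detect_episodes(variant)
            assert [c.flagged for c in alt] == [c.flagged for c in base]
            assert [c.p_value for c in alt] == [c.p_value for c in base]

    def test_too_few_contrasts_errors(self):
        frame = _calls_frame({"0-0.5": ["up", "ns"]})
        with pytest.raises(ValueError):
            detect_episodes(frame)


@pytest.fixture(scope="module")
def baseline_calls(mixed_sim):
    _, matrix, samples, _ = mixed_sim
    return run_baseline_contrasts(matrix, samples).calls


class TestTemporalSummaries:
    def test_divergence_totals_and_unique_conservation(self, baseline_calls):
        div = baseline_divergence_counts(baseline_calls)
        assert div.n_unique <= div.grand_total
        assert (div.per_day["n_sig"] <= len(baseline_calls)).all()
        assert div.grand_total == int(div.per_day["n_sig"].sum())

    def test_single_probe_significant_everywhere(self):
        frame = _calls_frame({f"0-{d}": ["up", "ns"] for d in [0.5, 1, 2, 3]})
        div = baseline_divergence_counts(frame)
        assert div.grand_total == 4
        assert div.n_unique == 1

    def test_all_ns_matrix_gives_zeroes_everywhere(self):
        frame = _calls_frame({"0-0.5": ["ns"] * 3, "0-1": ["ns"] * 3})
        div = baseline_divergence_counts(frame)
        assert div.grand_total == 0 and div.n_unique == 0
        assert times_significant_histogram(frame).empty
        records, curve = cumulative_first_detection(frame)
        assert records.empty
        assert curve["cumulative"].tolist() == [0, 0]

    def test_first_detection_curve_monotone_and_conserved(self, baseline_calls):
        records, curve = cumulative_first_detection(baseline_calls)
        div = baseline_divergence_counts(baseline_calls)
        assert (curve["cumulative"].diff().dropna() >= 0).all()
        assert curve["cumulative"].iloc[-1] == div.n_unique
        assert len(records) == div.n_unique

    def test_probe_significant_only_at_day_10(self):
        labels = [f"0-{d:g}" for d in [0.5, 5, 10, 20]]
        frame = _calls_frame({lab: (["down"] if lab == "0-10" else ["ns"]) for lab in labels})
        records, _ = cumulative_first_detection(frame)
        assert records["earliest_day"].tolist() == [10.0]

    def test_immediate_early_probes_first_detected_at_half_day(self, mixed_sim):
        # oracle power at these settings is ~0.92 (see differential tests);
        # require a clear majority to be first detected at 0.5 DPA
        _, matrix, samples, truth = mixed_sim
        calls = run_baseline_contrasts(matrix, samples).calls
        records, _ = cumulative_first_detection(calls)
        ie = set(truth.probes.loc[truth.probes["archetype"] == "immediate_early", "probe_id"])
        early = records[records["probe_id"].isin(ie)]
        assert len(early) / len(ie) > 0.85
        assert (early["earliest_day"] == 0.5).mean() > 0.85

    def test_times_significant_histogram_support_and_mass(self, baseline_calls):
        hist = times_significant_histogram(baseline_calls)
        div = baseline_divergence_counts(baseline_calls)
        assert hist.sum() == div.n_unique
        assert hist.index.min() >= 1
        assert hist.index.max() <= baseline_calls.shape[1]

    def test_probe_significant_seven_of_nineteen_lands_in_bin_seven(self):
        labels = [f"0-{i}" for i in range(1, 20)]
        row = ["up"] * 7 + ["ns"] * 12
        frame = _calls_frame({lab: [v] for lab, v in zip(labels, row)})
        hist = times_significant_histogram(frame)
        assert hist.to_dict() == {7: 1}


class TestPairedCountProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    calls = st.lists(st.sampled_from(["up", "down", "ns"]), min_size=1, max_size=60)

    @given(data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_counts_partition_universe_and_direction_is_sign_of_c_minus_b(self, data):
        earlier = data.draw(self.calls)
        later = data.draw(self.st.lists(
            self.st.sampled_from(["up", "down", "ns"]),
            min_size=len(earlier), max_size=len(earlier),
        ))
        paired = paired_significance_counts(
            _series(earlier, "e"), _series(later, "l")
        )
        assert paired.a + paired.b + paired.c + paired.d == len(earlier)
        assert min(paired.a, paired.b, paired.c, paired.d) >= 0
        res = mcnemar_test(paired)
        expected = (
            "increase" if paired.c > paired.b
            else "decrease" if paired.b > paired.c
            else "none"
        )
        assert res.direction == expected
        assert 0.0 <= res.p_value <= 1.0
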