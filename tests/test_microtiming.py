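"""MTD statistics: deviations, sigma, swing ratio, serial correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swingtiming import (
    NoteClass,
    SynthSpec,
    analyze_performance,
    compute_class_means,
    compute_mtds,
    generate_performance,
    serial_correlations,
    summarize,
    swing_ratio,
    swing_ratios,
    table1_report,
    ticks_to_ms,
)
from swingtiming.microtiming import deviations_to_frame

from conftest import make_performance


def spearman_oracle(x, y):
    """Rank (average ties) then Pearson — the definitional Spearman."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestDeviations:
    def test_class_deviations_are_mean_zero(self, jittered_perf):
        devs = compute_mtds(jittered_perf)
        for klass in (NoteClass.BASE, NoteClass.SWING):
            d = [dv.d for dv in devs if dv.klass is klass]
            assert np.mean(d) == pytest.approx(0.0, abs=1e-9)

    def test_deviation_is_offset_minus_class_mean(self):
        perf = make_performance([960 + 10, 1920 + 20, 960 + 640, 1920 + 640])
        devs = compute_mtds(perf)  # b_bar offset = 15
        base = sorted(dv.d for dv in devs if dv.klass is NoteClass.BASE)
        assert base == [-5, 5]

    def test_note_at_its_class_mean_has_zero_deviation(self):
        perf = make_performance([960 + 10, 1920 + 10, 960 + 640, 1920 + 640])
        devs = compute_mtds(perf)
        assert all(dv.d == 0 for dv in devs if dv.klass is NoteClass.BASE)

    def test_disregarded_notes_get_no_deviation(self):
        perf = make_performance([0, 320, 640, 960, 960 + 640])
        devs = compute_mtds(perf)
        assert len(devs) == 4
        assert all(dv.klass is not NoteClass.DISREGARDED for dv in devs)


class TestSummaries:
    def test_zero_deviations_give_zero_sigma(self, quantized_perf):
        devs = compute_mtds(quantized_perf)
        sigma_b, sigma_s, mean_ms = summarize(devs, quantized_perf.bpm)
        assert sigma_b == 0 and sigma_s == 0
        assert mean_ms == pytest.approx(0, abs=1e-12)

    def test_sigma_uses_n_minus_1_and_ms_units(self):
        perf = make_performance([960 - 12, 1920 + 12, 960 + 640, 1920 + 640], bpm=60)
        devs = compute_mtds(perf)
        sigma_b, _, _ = summarize(devs, 60.0)
        # base deviations are {-12, +12}: sd with n-1 divisor is 16.97 ticks
        expected = ticks_to_ms(np.std([-12, 12], ddof=1), 60.0)
        assert sigma_b == pytest.approx(expected, rel=1e-12)

    def test_single_note_class_reported_missing(self):
        perf = make_performance([960, 960 + 640, 1920 + 640])
        sigma_b, sigma_s, _ = summarize(compute_mtds(perf), 120.0)
        assert sigma_b is None
        assert sigma_s is not None

    def test_iid_gaussian_sigma_recovered_within_3_se(self):
        sigma = 18.39
        n = 5000
        res = generate_performance(
            SynthSpec(
                n_quarters=n // 2,
                sigma_ms=sigma,
                noise_model="iid_gaussian",
                chord_prob=0,
                middle_note_frac=0,
                seed=7,
            )
        )
        prof = analyze_performance(res.performance)
        pooled = prof.pooled_deviations_ms()
        se = sigma / np.sqrt(2 * pooled.size)
        assert np.std(pooled, ddof=1) == pytest.approx(sigma, abs=3 * se)


class TestSwingRatio:
    def test_perfect_triplets_give_exactly_two(self):
        r, delta = swing_ratio([640, 960 + 640, 5 * 960 + 640])
        assert r == 2.0
        assert delta == 0.0

    def test_straight_eighths_midpoint_gives_one(self):
        assert swing_ratios([480])[0] == 1.0

    def test_per_note_ratio_at_582(self):
        # ratio at the mean position differs from the mean of per-note ratios
        assert swing_ratios([582])[0] == pytest.approx(582 / 378, rel=1e-12)

    def test_strictly_increasing_in_position(self, rng):
        p = np.sort(rng.uniform(1, 959, size=200))
        r = swing_ratios(p)
        assert np.all(np.diff(r) > 0)

    def test_mean_of_ratios_exceeds_ratio_of_mean_under_symmetric_jitter(self):
        # Jensen: r(p) is convex, so jitter inflates the average ratio
        jitter = np.array([-60, -30, 0, 30, 60])
        r_jittered, _ = swing_ratio(640 + jitter)
        assert r_jittered > 2.0

    def test_residue_on_grid_boundary_rejected(self):
        with pytest.raises(ValueError):
            swing_ratios([960])
        with pytest.raises(ValueError):
            swing_ratios([0])


class TestSerialCorrelations:
    def test_identical_ranks_give_plus_one(self):
        # monotone deviations: every pair (this bin, next bin) increases,
        # so both directions have perfectly concordant ranks
        devs = [-15, -9, -3, 3, 9, 15]
        onsets = []
        for q, d in enumerate(devs):
            onsets += [960 * (q + 1) + d, 960 * (q + 1) + 640 + d]
        perf = make_performance(onsets)
        rho_bs, rho_sb = serial_correlations(compute_mtds(perf))
        assert rho_bs == pytest.approx(1.0)
        assert rho_sb == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        base_dev = [-15, -9, -3, 3, 9, 15]
        swing_dev = [-d for d in base_dev]
        onsets = []
        for q, (db, ds) in enumerate(zip(base_dev, swing_dev)):
            onsets += [960 * (q + 1) + db, 960 * (q + 1) + 640 + ds]
        perf = make_performance(onsets)
        rho_bs, _ = serial_correlations(compute_mtds(perf))
        assert rho_bs == pytest.approx(-1.0)

    def test_too_few_pairs_reported_missing(self):
        perf = make_performance([960, 960 + 640, 1920, 1920 + 640])
        rho_bs, rho_sb = serial_correlations(compute_mtds(perf))
        assert rho_bs is None and rho_sb is None

    def test_pairs_respect_quarter_note_distance(self):
        # base and swing notes in quarters 1..3 only: three b->s pairs
        # (base q with swing q, 640 ticks later) but just two s->b pairs
        # (swing q with base q+1), which is below the reporting minimum
        onsets = []
        for q in range(1, 4):
            onsets.append(960 * q + [3, 1, 4][q - 1])
            onsets.append(960 * q + 640 + [2, 7, 1][q - 1])
        perf = make_performance(onsets)
        rho_bs, rho_sb = serial_correlations(compute_mtds(perf))
        assert rho_bs is not None
        assert rho_sb is None

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(-30, 30), st.integers(-30, 30)),
            min_size=3,
            max_size=25,
        )
    )
    def test_spearman_matches_rank_then_pearson_oracle(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return  # degenerate: correlation undefined
        onsets = []
        for q, (db, ds) in enumerate(data):
            onsets += [960 * (q + 1) + db, 960 * (q + 1) + 640 + ds]
        perf = make_performance(onsets)
        rho_bs, _ = serial_correlations(compute_mtds(perf))
        # pairing (d_b, d_s) preserves the rank pattern of (x, y)
        assert rho_bs == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_negating_both_members_leaves_rho_unchanged(self, rng):
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        assert spearman_oracle(-x, -y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestReport:
    def test_perfectly_quantized_row(self, quantized_perf):
        report = table1_report([quantized_perf], names=["perfect"])
        row = report.iloc[0]
        assert row["b_bar"] == 0
        assert row["s_bar"] == 640
        assert row["sigma_b_ms"] == 0
        assert row["r"] == 2.0
        assert row["delta_r"] == 0.0
        assert pd.isna(row["rho_b_to_s"])

    def test_failures_become_nan_rows_not_aborts(self, quantized_perf):
        broken = make_performance([0, 960, 1920])  # no swing notes at all
        report = table1_report([quantized_perf, broken], names=["ok", "broken"])
        assert len(report) == 2
        assert np.isnan(report.iloc[1]["s_bar"])

    def test_deviation_frame_units(self, jittered_perf):
        prof = analyze_performance(jittered_perf)
        frame = deviations_to_frame(prof)
        assert np.allclose(
            frame["d_ms"], ticks_to_ms(frame["d_ticks"].to_numpy(), jittered_perf.bpm)
        )

    def test_sigma_mode_all_counts_every_chord_tone(self):
        # chord bin at +30/+40: 'bin' sees base offsets {0, 30}; 'all' sees {0, 30, 40}
        onsets = [960, 960 + 640, 1920 + 30, 1920 + 40, 1920 + 640, 2880, 2880 + 640]
        perf = make_performance(onsets)
        prof_bin = analyze_performance(perf, sigma_mode="bin")
        prof_all = analyze_performance(perf, sigma_mode="all")
        assert prof_bin.sigma_b_ms != prof_all.sigma_b_ms

    def test_middle_fraction_counted(self):
        perf = make_performance([960, 960 + 320, 960 + 640, 1920, 1920 + 640])
        prof = analyze_performance(perf)
        assert prof.middle_fraction == pytest.approx(1 / 5)
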