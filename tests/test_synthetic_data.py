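import math

import numpy as np
import pytest
from scipy import stats

from porestep import (
    TraceParams,
    draw_capture_times,
    draw_event,
    draw_events,
    draw_gdnhcl_event,
    fraction_below_resolution,
    hypoexp_mean,
    render_trace,
)


class TestDrawEvent:
    def test_level5_dwell_mean_matches_rate(self, y18):
        # level 5 is the slow unfolding of the central beta-sheet core
        rng = np.random.default_rng(10)
        dwells = [draw_event(y18, rng).levels[4].dwell_s for _ in range(10_000)]
        assert np.mean(dwells) == pytest.approx(1 / 0.98, rel=0.02)

    def test_dwells_positive_currents_within_pore(self, y18, y26):
        rng = np.random.default_rng(11)
        for scheme in (y18, y26):
            for _ in range(200):
                ev = draw_event(scheme, rng)
                assert all(lv.dwell_s > 0 for lv in ev.levels)
                assert all(0 < lv.current_pa < scheme.open_pore_pa for lv in ev.levels)
                assert [lv.ordinal for lv in ev.levels] == list(range(1, 8))

    def test_sub_resolution_level1_fraction(self, y18):
        # fast first level: ~7% of dwells fall under the 0.2 ms resolution
        rng = np.random.default_rng(12)
        n = 10_000
        short = sum(draw_event(y18, rng).levels[0].dwell_s < 2e-4 for _ in range(n))
        expected = fraction_below_resolution(379, 2e-4)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(short / n - expected) < 3 * se

    def test_reproducible_under_seed(self, y18):
        a = draw_event(y18, np.random.default_rng(7))
        b = draw_event(y18, np.random.default_rng(7))
        assert a == b


class TestDrawGdnhclEvent:
    def test_exactly_four_canonical_levels(self, y18):
        rng = np.random.default_rng(13)
        for _ in range(100):
            ev = draw_gdnhcl_event(y18, rng)
            ords = [lv.ordinal for lv in ev.levels]
            assert ords[:4] == [1, 2, 3, 4]
            assert all(o == 0 for o in ords[4:])
            assert ev.gdnhcl_mode
            assert 3 <= len(ords) - 4 <= 10

    def test_median_duration_twice_canonical(self, y18):
        # denaturant events last ~2x the canonical median (1.93 vs 0.99 s)
        rng = np.random.default_rng(14)
        gdn = np.array([draw_gdnhcl_event(y18, rng).total_duration_s for _ in range(10_000)])
        can = np.array([draw_event(y18, rng).total_duration_s for _ in range(10_000)])
        ratio = np.median(gdn) / np.median(can)
        assert 1.8 < ratio < 2.2

    def test_segment_count_varies_across_seeds(self, y18):
        counts = {
            len(draw_gdnhcl_event(y18, np.random.default_rng(s)).levels) for s in range(20)
        }
        assert len(counts) > 1


class TestDrawCaptureTimes:
    def test_zero_rate_empty(self):
        assert draw_capture_times(0.0, 600, np.random.default_rng(0)) == []

    def test_strictly_increasing(self):
        times = draw_capture_times(55, 600, np.random.default_rng(1))
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_poisson_mean_count(self):
        # 12 events/min for 10 min -> 120 expected captures
        counts = [
            len(draw_capture_times(12, 600, np.random.default_rng(s))) for s in range(400)
        ]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - 120) < 3 * se


class TestRenderTrace:
    def test_noiseless_render_is_exact(self, y18):
        rng = np.random.default_rng(20)
        plan = draw_event(y18, rng)
        params = TraceParams(noise_sd_pa=0.0, filter_cutoff_hz=None, duration_s=5.0)
        rec = render_trace([plan], [1.0], params, rng)
        assert len(rec.samples) == params.n_samples
        (ev,) = rec.ground_truth
        for (ordinal, a, b), lv in zip(ev.level_spans, plan.levels):
            assert ordinal == lv.ordinal
            assert np.all(rec.samples[a:b] == lv.current_pa)

    def test_ground_truth_spans_tile_event(self, y18):
        rng = np.random.default_rng(21)
        plans, _ = draw_events(y18, 5, rng)
        params = TraceParams(duration_s=30.0)
        rec = render_trace(plans, [2.0, 8.0, 14.0, 20.0, 26.0], params, rng)
        for ev in rec.ground_truth:
            spans = ev.level_spans
            assert spans[0][1] == ev.start_index
            assert spans[-1][2] == ev.end_index
            for (_, _, e1), (_, s2, _) in zip(spans, spans[1:]):
                assert e1 == s2

    def test_open_pore_level_and_sample_count(self):
        params = TraceParams(duration_s=10.0, filter_cutoff_hz=None)
        rec = render_trace([], [], params, np.random.default_rng(22))
        assert len(rec.samples) == round(10.0 * 20_000)
        assert np.mean(rec.samples) == pytest.approx(230.0, rel=1e-3)

    def test_overflowing_event_dropped(self, y18):
        rng = np.random.default_rng(23)
        plan = draw_event(y18, rng)
        params = TraceParams(duration_s=0.5)
        rec = render_trace([plan], [0.45], params, rng)
        assert rec.ground_truth == []

    def test_bit_reproducible(self, y18):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            plans, _ = draw_events(y18, 3, rng)
            rec = render_trace(plans, [1.0, 4.0, 7.0], TraceParams(duration_s=12.0), rng)
            out.append(rec.samples)
        assert np.array_equal(out[0], out[1])

    def test_noise_is_gaussian_about_ground_truth(self, y18):
        # unfiltered residuals about the true level means: N(0, noise_sd)
        rng = np.random.default_rng(24)
        plans, _ = draw_events(y18, 3, rng)
        params = TraceParams(noise_sd_pa=2.0, filter_cutoff_hz=None, duration_s=8.0)
        rec = render_trace(plans, [1.0, 3.5, 6.0], params, rng)
        truth = np.full(len(rec.samples), 230.0)
        for ev in rec.ground_truth:
            for (_, a, b), lv in zip(ev.level_spans, ev.plan.levels):
                truth[a:b] = lv.current_pa
        resid = (rec.samples - truth)[:100_000]
        _, p = stats.kstest(resid, "norm", args=(0.0, 2.0))
        assert p > 0.01


class TestDurationConsistency:
    def test_mean_total_duration_matches_hypoexponential(self, y18, y26):
        for scheme in (y18, y26):
            rng = np.random.default_rng(25)
            totals = np.array(
                [draw_event(scheme, rng).total_duration_s for _ in range(10_000)]
            )
            se = totals.std(ddof=1) / math.sqrt(len(totals))
            assert abs(totals.mean() - hypoexp_mean(scheme)) < 3 * se


class TestFractionBelowResolution:
    def test_closed_form_values(self):
        assert fraction_below_resolution(380, 2e-4) == pytest.approx(
            1 - math.exp(-0.076), abs=1e-12
        )
        assert fraction_below_resolution(380, 2e-4) == pytest.approx(0.0732, abs=5e-4)
        assert fraction_below_resolution(443, 2e-4) == pytest.approx(0.0849, abs=5e-4)

    def test_zero_resolution(self):
        assert fraction_below_resolution(1000.0, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fraction_below_resolution(-1.0, 1e-4)
        with pytest.raises(ValueError):
            fraction_below_resolution(10.0, -1e-4)
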