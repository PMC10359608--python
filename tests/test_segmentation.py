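import numpy as np
import pytest

from porestep import (
    TraceParams,
    draw_event,
    draw_events,
    draw_gdnhcl_event,
    render_single_event,
    render_trace,
    scheme_for,
)
from porestep.segmentation import (
    MIN_DWELL_S,
    LevelCall,
    assign_ordinals,
    best_template_assignment,
    detect_events,
    extract_dwell_table,
    idealize_event,
    residual_percent,
)

FS = 20_000.0

Y18_TEMPLATE = (50.5, 15.5, 9.5, 1.3, 14.2, 10.8, 2.6)


def _noiseless_params(open_pore=230.0):
    return TraceParams(noise_sd_pa=0.0, filter_cutoff_hz=None, open_pore_pa=open_pore)


def _draw_resolvable_event(scheme, rng, min_dwell=0.002):
    """Redraw until every level is comfortably above the time resolution."""
    while True:
        plan = draw_event(scheme, rng)
        if all(lv.dwell_s >= min_dwell for lv in plan.levels):
            return plan


class TestDetectEvents:
    def test_noiseless_windows_match_ground_truth(self, y18):
        rng = np.random.default_rng(30)
        plans, _ = draw_events(y18, 3, rng)
        params = TraceParams(noise_sd_pa=0.0, filter_cutoff_hz=None, duration_s=20.0)
        rec = render_trace(plans, [2.0, 8.0, 14.0], params, rng)
        windows = detect_events(rec)
        assert len(windows) == 3
        for (a, b), ev in zip(windows, rec.ground_truth):
            assert (a, b) == (ev.start_index, ev.end_index)

    def test_open_pore_only_trace(self):
        rec = render_trace([], [], TraceParams(duration_s=2.0), np.random.default_rng(31))
        assert detect_events(rec) == []

    def test_noisy_windows_cover_truth_within_two_samples(self, y18):
        rng = np.random.default_rng(32)
        plans, _ = draw_events(y18, 60, rng)
        starts = np.cumsum([2.0] + [p.total_duration_s + 1.0 for p in plans[:-1]])
        duration = starts[-1] + plans[-1].total_duration_s + 2.0
        params = TraceParams(duration_s=float(duration))
        rec = render_trace(plans, list(starts), params, rng)
        windows = detect_events(rec)
        assert len(windows) == len(rec.ground_truth) == 60
        for (a, b), ev in zip(windows, rec.ground_truth):
            assert abs(a - ev.start_index) <= 2
            assert abs(b - ev.end_index) <= 2

    def test_empty_trace_errors(self):
        rec = render_trace([], [], TraceParams(duration_s=1.0), np.random.default_rng(0))
        rec.samples = rec.samples[:0]
        with pytest.raises(ValueError):
            detect_events(rec)

    def test_threshold_validated(self, y18):
        rec = render_trace([], [], TraceParams(duration_s=1.0), np.random.default_rng(0))
        with pytest.raises(ValueError):
            detect_events(rec, threshold_frac=1.2)


class TestIdealizeEvent:
    def test_noiseless_event_exact(self, y18):
        rng = np.random.default_rng(33)
        plan = _draw_resolvable_event(y18, rng)
        rec = render_single_event(plan, _noiseless_params(), rng)
        (ev,) = rec.ground_truth
        calls = idealize_event(rec.samples[ev.start_index : ev.end_index], FS)
        assert len(calls) == 7
        for call, (_, a, b), lv in zip(calls, ev.level_spans, ev.plan.levels):
            assert call.mean_pa == pytest.approx(lv.current_pa, abs=1e-12)
            assert round(call.start_s * FS) == a - ev.start_index
            assert round(call.end_s * FS) == b - ev.start_index

    def test_noisy_event_means_within_half_picoamp(self, y18):
        # >=5 ms per level so each segment mean has SE well below 0.5 pA
        rng = np.random.default_rng(34)
        plan = _draw_resolvable_event(y18, rng, min_dwell=0.005)
        rec = render_single_event(plan, TraceParams(open_pore_pa=230.0), rng)
        (ev,) = rec.ground_truth
        calls = idealize_event(rec.samples[ev.start_index : ev.end_index], FS)
        assert len(calls) == 7
        for call, lv in zip(calls, plan.levels):
            assert call.mean_pa == pytest.approx(lv.current_pa, abs=0.5)

    def test_sub_resolution_level_merges_away(self, y18):
        # a 0.1 ms first level is below the resolution and must disappear
        rng = np.random.default_rng(35)
        plan = draw_event(y18, rng)
        levels = (plan.levels[0].__class__(1, 0.0001, plan.levels[0].current_pa),) + plan.levels[1:]
        plan = plan.__class__(plan.construct_label, levels)
        rec = render_single_event(plan, _noiseless_params(), rng)
        (ev,) = rec.ground_truth
        calls = idealize_event(rec.samples[ev.start_index : ev.end_index], FS)
        assert len(calls) == 6
        ideal = assign_ordinals(calls, Y18_TEMPLATE, 230.0)
        assert ideal.missing_level1
        assert ideal.canonical

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            idealize_event(np.ones(3), FS, min_dwell_s=MIN_DWELL_S)

    def test_idempotent_on_reconstruction(self, y18):
        rng = np.random.default_rng(36)
        plan = draw_event(y18, rng)
        rec = render_single_event(plan, TraceParams(), rng)
        (ev,) = rec.ground_truth
        window = rec.samples[ev.start_index : ev.end_index]
        calls = idealize_event(window, FS)
        recon = np.concatenate(
            [np.full(round((c.end_s - c.start_s) * FS), c.mean_pa) for c in calls]
        )
        again = idealize_event(recon, FS)
        assert [round(c.end_s * FS) for c in again] == [round(c.end_s * FS) for c in calls]
        assert [round(c.start_s * FS) for c in again] == [round(c.start_s * FS) for c in calls]


class TestAssignOrdinals:
    def _calls(self, ires_values, open_pore=230.0, dwell=0.01):
        calls = []
        t = 0.0
        for r in ires_values:
            calls.append(LevelCall(0, t, t + dwell, r / 100.0 * open_pore))
            t += dwell
        return calls

    def test_published_ladder_is_canonical(self):
        ideal = assign_ordinals(self._calls((50.5, 15.5, 9.5, 1.3, 14.2, 10.8, 2.6)),
                                Y18_TEMPLATE, 230.0)
        assert ideal.canonical
        assert not ideal.missing_level1
        assert [c.ordinal for c in ideal.level_calls] == list(range(1, 8))

    def test_missing_first_level_detected(self):
        ideal = assign_ordinals(self._calls((15.5, 9.5, 1.3, 14.2, 10.8, 2.6)),
                                Y18_TEMPLATE, 230.0)
        assert ideal.canonical
        assert ideal.missing_level1
        assert [c.ordinal for c in ideal.level_calls] == list(range(2, 8))

    def test_gdnhcl_event_not_canonical(self, y18):
        rng = np.random.default_rng(37)
        plan = draw_gdnhcl_event(y18, rng)
        rec = render_single_event(plan, _noiseless_params(), rng)
        (ev,) = rec.ground_truth
        calls = idealize_event(rec.samples[ev.start_index : ev.end_index], FS)
        ideal = assign_ordinals(calls, Y18_TEMPLATE, 230.0)
        assert not ideal.canonical
        # the canonical head (levels 1-4) is still recognized
        assert [c.ordinal for c in ideal.level_calls[:4]] == [1, 2, 3, 4]

    def test_template_deviation_breaks_canonicality(self):
        values = (50.5, 15.5, 9.5, 1.3, 22.0, 10.8, 2.6)  # level 5 off by 7.8
        ideal = assign_ordinals(self._calls(values), Y18_TEMPLATE, 230.0)
        assert not ideal.canonical

    def test_best_template_prefers_matching_construct(self, y26):
        values = (48.7, 13.7, 15.0, 1.3, 15.1, 11.8, 2.8)
        templates = {"Y18": Y18_TEMPLATE, "Y26": y26.level_residuals}
        ideal, key = best_template_assignment(self._calls(values), templates, 230.0)
        assert key == "Y26"
        assert ideal.canonical


class TestResidualPercent:
    @pytest.mark.parametrize(
        "mean,open_pore,expected", [(230, 230, 100.0), (0, 230, 0.0), (116.15, 230, 50.5)]
    )
    def test_values(self, mean, open_pore, expected):
        assert residual_percent(mean, open_pore) == pytest.approx(expected)

    def test_scale_invariance(self):
        for alpha in (0.5, 2.0, 17.3):
            assert residual_percent(40.0 * alpha, 230.0 * alpha) == pytest.approx(
                residual_percent(40.0, 230.0)
            )

    def test_nonpositive_open_pore(self):
        with pytest.raises(ValueError):
            residual_percent(10.0, 0.0)


class TestDwellTableAndRecovery:
    def test_canonical_dwells_sum_to_total(self, segmented_y18):
        _, ideals, table = segmented_y18
        full = table[table["canonical"] & ~table["missing_level1"]]
        dwell_cols = [f"dwell_{i}" for i in range(1, 8)]
        sums = full[dwell_cols].sum(axis=1)
        assert np.allclose(sums, full["total_duration_s"], atol=1e-9)

    def test_recovery_rate_at_least_99_percent(self, segmented_y18):
        # events whose levels are all resolvable must come back canonical
        plans, ideals, table = segmented_y18
        resolvable = [
            all(lv.dwell_s >= MIN_DWELL_S for lv in plan.levels[1:]) for plan in plans
        ]
        got = table["canonical"].to_numpy()
        n_res = sum(resolvable)
        n_ok = sum(c for c, r in zip(got, resolvable) if r)
        assert n_res > 250
        assert n_ok / n_res >= 0.99

    def test_segmented_dwell_means_match_rates(self, segmented_y18, y18):
        # mean dwell per level ~ 1/k within 3 standard errors
        _, _, table = segmented_y18
        canonical = table[table["canonical"]]
        for lvl, k in zip(range(1, 8), y18.step_rates):
            d = canonical[f"dwell_{lvl}"].dropna().to_numpy()
            d = d[d >= MIN_DWELL_S]
            se = d.std(ddof=1) / np.sqrt(len(d))
            # the sub-resolution cut biases the mean up by at most t_res
            assert abs(d.mean() - 1 / k) < 3 * se + MIN_DWELL_S

    def test_missing_level1_row_has_nan_dwell1(self):
        calls = [
            LevelCall(0, i * 0.01, (i + 1) * 0.01, r / 100 * 230)
            for i, r in enumerate((15.5, 9.5, 1.3, 14.2, 10.8, 2.6))
        ]
        ideal = assign_ordinals(calls, Y18_TEMPLATE, 230.0)
        table = extract_dwell_table([ideal])
        assert np.isnan(table.loc[0, "dwell_1"])
        assert table.loc[0, "missing_level1"].item()
        assert table[[f"dwell_{i}" for i in range(2, 8)]].notna().all(axis=None)
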