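"""End-to-end analysis driver: simulate -> segment -> fit -> classify.

One :class:`RunConfig` describes a complete in-silico experiment — which
construct, at what voltage, how many events, rendered to sampled traces
or kept as direct dwell draws — and :func:`run_pipeline` executes every
applicable stage, returning (and optionally writing) a single report.
Every stochastic stage is seeded from the root seed, so two runs with the
same config produce identical tables and JSON (timestamps are isolated in
one field).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .dwell_kinetics import (
    FitError,
    RateFit,
    build_loghist,
    fit_double_loghist,
    fit_mono_loghist,
    select_model,
)
from .kinetic_scheme import MixtureScheme, RateTable, default_registry, scheme_for
from .population import classify_events, event_features, summarize_durations
from .segmentation import (
    MIN_DWELL_S,
    best_template_assignment,
    detect_events,
    extract_dwell_table,
    idealize_event,
    level_table,
)
from .synthetic_data import (
    TraceParams,
    draw_events,
    dwell_table_from_plans,
    render_single_event,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated-experiment analysis run."""

    construct: str = "Y18"
    voltage_mv: float = 120.0
    n_events: int = 300
    seed: int = 0
    render: bool = False  # render traces and re-segment, or fit true dwells
    gdnhcl: bool = False
    noise_sd_pa: float = 2.0
    filter_cutoff_hz: float | None = 5000.0
    sampling_rate_hz: float = 20_000.0
    threshold_frac: float = 0.8
    min_dwell_s: float = MIN_DWELL_S
    n_bins: int = 30
    kmeans_restarts: int = 10
    registry_path: str | None = None

    def registry(self) -> RateTable:
        from .kinetic_scheme import load_registry

        return load_registry(self.registry_path) if self.registry_path else default_registry()


def _fit_level(
    dwells: np.ndarray, n_bins: int, min_dwell_s: float, try_double: bool
) -> dict | None:
    """Mono (and optionally double) fit of one level's dwell set."""
    d = dwells[np.isfinite(dwells)]
    d = d[d >= min_dwell_s]  # sub-resolution dwells cannot occur in real data
    if d.size < 20:
        return None
    hist = build_loghist(d, n_bins)
    try:
        mono = fit_mono_loghist(hist)
    except FitError as exc:
        logger.warning("mono fit failed: %s", exc)
        return None
    chosen: RateFit = mono
    if try_double and d.size >= 50:
        try:
            double = fit_double_loghist(hist)
            if select_model(mono, double) == "double":
                chosen = double
        except FitError as exc:
            logger.warning("double fit failed: %s", exc)
    return {
        "model": chosen.model,
        "rates_s": list(chosen.rates),
        "weights": list(chosen.weights),
        "ci95": [list(c) for c in chosen.ci95],
        "n": chosen.n,
        "bic": chosen.bic,
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every applicable stage and return the report dictionary.

    With ``outdir`` the report (JSON) and the dwell/level/label tables
    (TSV) are also written there.
    """
    reg = config.registry()
    scheme = scheme_for(config.construct, config.voltage_mv, reg)
    rng = np.random.default_rng(config.seed)
    plans, labels = draw_events(scheme, config.n_events, rng, gdnhcl=config.gdnhcl)

    levels_df: pd.DataFrame | None = None
    if config.render:
        params = TraceParams(
            sampling_rate_hz=config.sampling_rate_hz,
            filter_cutoff_hz=config.filter_cutoff_hz,
            noise_sd_pa=config.noise_sd_pa,
            open_pore_pa=reg.open_pore_pa(config.voltage_mv),
            voltage_mv=config.voltage_mv,
        )
        if isinstance(scheme, MixtureScheme):
            templates = {c.construct_id: c.level_residuals for c in scheme.components}
        else:
            templates = {scheme.construct_id: scheme.level_residuals}
        idealizations = []
        for i, plan in enumerate(plans):
            trace = render_single_event(plan, params, rng)
            windows = detect_events(trace, config.threshold_frac)
            if not windows:
                logger.warning("event %d not detected; skipped", i)
                continue
            a, b = max(windows, key=lambda w: w[1] - w[0])
            calls = idealize_event(
                trace.samples[a:b],
                config.sampling_rate_hz,
                config.min_dwell_s,
                offset_s=a / config.sampling_rate_hz,
            )
            ideal, _ = best_template_assignment(
                calls, templates, params.open_pore_pa, event_index=i
            )
            idealizations.append(ideal)
        dwell_table = extract_dwell_table(
            idealizations, labels=[labels[i.event_index] for i in idealizations],
            voltage_mv=config.voltage_mv,
        )
        levels_df = level_table(idealizations)
    else:
        dwell_table = dwell_table_from_plans(plans, labels, voltage_mv=config.voltage_mv)

    is_wt = config.construct == "wt"
    canonical = dwell_table[dwell_table["canonical"]]
    level_fits = {}
    for lvl in range(1, 8):
        fit = _fit_level(
            canonical[f"dwell_{lvl}"].to_numpy(float),
            config.n_bins,
            config.min_dwell_s,
            try_double=is_wt and lvl in (2, 3),
        )
        if fit is not None:
            level_fits[str(lvl)] = fit

    residuals = {}
    if config.render:
        for lvl in range(1, 8):
            vals = canonical[f"ires_{lvl}"].dropna()
            if len(vals):
                residuals[str(lvl)] = {
                    "mean_pct": float(vals.mean()),
                    "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }

    classification = None
    duration_summary = None
    if is_wt and not config.gdnhcl:
        feats, used, n_excl = event_features(dwell_table)
        if len(feats) >= 20:
            result = classify_events(feats, rng_seed=config.seed)
            dwell_table.loc[used, "assigned"] = list(result.labels)
            classification = {
                "fractions": result.fractions,
                "silhouette": result.silhouette,
                "n_classified": len(feats),
                "n_excluded": n_excl,
            }
            summary = summarize_durations(
                dwell_table.loc[used], group_by="assigned"
            )
            duration_summary = {
                "groups": summary.to_dict(orient="records"),
                "median_ratio": summary.attrs.get("median_ratio"),
            }

    report = {
        "config": dataclasses.asdict(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_events": int(len(dwell_table)),
        "n_canonical": int(dwell_table["canonical"].sum()),
        "n_missing_level1": int(dwell_table["missing_level1"].sum()),
        "level_fits": level_fits,
        "residual_currents": residuals,
        "classification": classification,
        "duration_summary": duration_summary,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        psio.write_json(report, out / "report.json")
        psio.write_table(dwell_table, out / "dwell_table.tsv")
        if levels_df is not None:
            psio.write_table(levels_df, out / "levels.tsv")
    return report
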