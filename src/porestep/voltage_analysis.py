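"""Voltage dependence of unfolding rates and capture frequency.

Across the +100..+140 mV working range the capture frequency grows
steeply with voltage (electrophoretic capture of the DNA leader) while
only the steps probing protein entry into the pore (2->3 and 3->4) show a
mild rate increase.  This module quantifies both: a Pearson trend of rate
against voltage with a least-squares slope, and the events-per-minute
capture frequency of a recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "rate_trend", "capture_frequency"]


@dataclass(frozen=True)
class TrendResult:
    """Rate-versus-voltage trend summary."""

    voltages_mv: tuple[float, ...]
    rates_s: tuple[float, ...]
    pearson_r: float
    slope: float  # s^-1 per mV
    intercept: float
    n_points: int
    degenerate: bool = False  # constant input: r undefined, not NaN-propagated
    ci95: tuple[tuple[float, float], ...] | None = None


def rate_trend(
    voltages_mv: Sequence[float],
    rates_s: Sequence[float],
    ci95: Sequence[tuple[float, float]] | None = None,
) -> TrendResult:
    """Pearson correlation and least-squares slope of rate against voltage.

    Constant rates (or voltages) make the correlation undefined; the
    result is then flagged degenerate with ``pearson_r = 0`` so pipelines
    never propagate NaN silently.
    """
    v = np.asarray(voltages_mv, dtype=float)
    k = np.asarray(rates_s, dtype=float)
    if v.size != k.size:
        raise ValueError("voltages and rates must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 points for a trend")
    order = np.argsort(v)
    v, k = v[order], k[order]
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be distinct")
    cis = tuple(tuple(c) for c in np.asarray(ci95, float)[order]) if ci95 is not None else None
    if np.std(k) == 0 or np.std(v) == 0:
        return TrendResult(
            voltages_mv=tuple(v),
            rates_s=tuple(k),
            pearson_r=0.0,
            slope=0.0,
            intercept=float(k.mean()),
            n_points=int(v.size),
            degenerate=True,
            ci95=cis,
        )
    r, _ = stats.pearsonr(v, k)
    fit = stats.linregress(v, k)
    return TrendResult(
        voltages_mv=tuple(v),
        rates_s=tuple(k),
        pearson_r=float(r),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(v.size),
        ci95=cis,
    )


def capture_frequency(n_events: int, trace_duration_s: float) -> float:
    """Capture frequency in events per minute."""
    if trace_duration_s <= 0:
        raise ValueError("trace duration must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return 60.0 * n_events / trace_duration_s
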