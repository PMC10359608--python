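"""Exponential dwell-time fitting on the natural-log time axis.

Single-channel dwell times from a one-step Markov exit are exponential;
histogrammed against ``x = ln(t)`` their density becomes

    pdf(x) = A * k * exp(x - k * exp(x)),

a peaked curve with its mode at ``x = -ln(k)``, which spreads decades of
dwell times over a readable axis (the Sigworth-Sine transform).  Fits are
least squares of bin counts against this curve, evaluated at bin centers,
as is conventional for such histograms; the exact exponential maximum-
likelihood estimate ``k = 1/mean`` serves as an independent cross-check,
and a two-component sum handles bimodal level populations (a wild-type
sample mixing two constructs).  Model choice between one and two
components is by BIC with a degeneracy guard on the rate ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LogDwellHistogram",
    "RateFit",
    "FitError",
    "build_loghist",
    "log_exp_pdf",
    "fit_mono_loghist",
    "fit_double_loghist",
    "mle_rate",
    "bootstrap_ci",
    "select_model",
]

#: Components whose rates differ by less than this factor are unresolvable.
DEGENERACY_RATIO = 3.0


class FitError(RuntimeError):
    """A dwell-distribution fit failed; the message carries diagnostics."""


@dataclass(frozen=True)
class LogDwellHistogram:
    """Histogram of ``ln(dwell)`` with raw counts."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need one count per bin")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def mean_dwell_s(self) -> float:
        """Histogram-weighted mean dwell time (seconds)."""
        if self.n_total == 0:
            raise ValueError("empty histogram")
        return float(np.sum(self.counts * np.exp(self.centers)) / self.n_total)


@dataclass(frozen=True)
class RateFit:
    """Result of a mono- or double-exponential log-dwell fit."""

    model: str  # "mono" | "double"
    rates: tuple[float, ...]  # descending for double (fast first)
    amplitudes: tuple[float, ...]
    weights: tuple[float, ...]  # amplitude shares, sum to 1
    ci95: tuple[tuple[float, float], ...]
    n: int
    sse: float
    bic: float
    degenerate: bool = False

    @property
    def rate(self) -> float:
        """Headline rate (the single rate of a mono fit)."""
        return self.rates[0]


def build_loghist(dwells: Sequence[float], n_bins: int = 30) -> LogDwellHistogram:
    """Histogram dwell times on the natural-log axis.

    Bins span ``[min, max]`` of ``ln(dwell)``; 30 bins give roughly ten
    bins per decade over a typical three-decade dwell range.
    """
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell set")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    x = np.log(d)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # all dwells equal: a single occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(x, edges)  # right edge included in last bin
    return LogDwellHistogram(bin_edges=edges, counts=counts.astype(float))


def log_exp_pdf(x: np.ndarray, amplitude: float, rate: float) -> np.ndarray:
    """``A * k * exp(x - k * e^x)``, the exponential pdf in log time."""
    return amplitude * rate * np.exp(x - rate * np.exp(x))


def _bic(sse: float, n_points: int, n_params: int) -> float:
    sse = max(sse, 1e-300)
    return n_points * math.log(sse / n_points) + n_params * math.log(n_points)


def fit_mono_loghist(hist: LogDwellHistogram, min_events: int = 20) -> RateFit:
    """Least-squares mono-exponential fit of a log-dwell histogram.

    Initialized at the 1/mean estimate; amplitude and rate free, rate
    positive.
    """
    if hist.n_total < min_events:
        raise FitError(f"too few events for a mono fit ({hist.n_total} < {min_events})")
    k0 = 1.0 / hist.mean_dwell_s
    a0 = hist.n_total * hist.bin_width
    try:
        popt, pcov = curve_fit(
            log_exp_pdf,
            hist.centers,
            hist.counts,
            p0=[a0, k0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"mono fit did not converge: {exc}") from exc
    amp, k = float(popt[0]), float(popt[1])
    resid = hist.counts - log_exp_pdf(hist.centers, amp, k)
    sse = float(np.sum(resid**2))
    k_se = math.sqrt(max(pcov[1, 1], 0.0)) if np.isfinite(pcov[1, 1]) else float("nan")
    ci = (max(k - 1.96 * k_se, 0.0), k + 1.96 * k_se)
    return RateFit(
        model="mono",
        rates=(k,),
        amplitudes=(amp,),
        weights=(1.0,),
        ci95=(ci,),
        n=hist.n_total,
        sse=sse,
        bic=_bic(sse, len(hist.counts), 2),
    )


def _double_pdf(x: np.ndarray, a1: float, k1: float, a2: float, k2: float) -> np.ndarray:
    return log_exp_pdf(x, a1, k1) + log_exp_pdf(x, a2, k2)


def _split_init(hist: LogDwellHistogram) -> tuple[float, float, float, float]:
    """Initial guesses from a count-weighted 1-D two-means split of ln(t)."""
    x = hist.centers
    w = hist.counts
    order = np.argsort(x)
    x, w = x[order], w[order]
    total = w.sum()
    best_i, best_cost = None, np.inf
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)
    for i in range(1, len(x)):
        wl, wr = cw[i - 1], total - cw[i - 1]
        if wl <= 0 or wr <= 0:
            continue
        sl, sr = cwx[i - 1], cwx[-1] - cwx[i - 1]
        ql, qr = cwx2[i - 1], cwx2[-1] - cwx2[i - 1]
        cost = (ql - sl * sl / wl) + (qr - sr * sr / wr)
        if cost < best_cost:
            best_cost, best_i = cost, i
    i = best_i if best_i is not None else len(x) // 2
    wl = cw[i - 1]
    wr = total - wl
    mean_l = float(np.sum(w[:i] * np.exp(x[:i])) / wl)
    mean_r = float(np.sum(w[i:] * np.exp(x[i:])) / wr)
    k_fast, k_slow = 1.0 / mean_l, 1.0 / mean_r
    a = hist.n_total * hist.bin_width
    return a * wl / total, k_fast, a * wr / total, k_slow


def fit_double_loghist(hist: LogDwellHistogram, min_events: int = 50) -> RateFit:
    """Least-squares two-component fit; components ordered fast, slow.

    Flagged degenerate when the fitted rates differ by less than a factor
    of :data:`DEGENERACY_RATIO` (the histogram cannot resolve them).
    """
    if hist.n_total < min_events:
        raise FitError(f"too few events for a double fit ({hist.n_total} < {min_events})")
    a1, k1, a2, k2 = _split_init(hist)
    try:
        popt, pcov = curve_fit(
            _double_pdf,
            hist.centers,
            hist.counts,
            p0=[a1, k1, a2, k2],
            bounds=([0.0, 1e-12, 0.0, 1e-12], [np.inf] * 4),
            maxfev=40000,
        )
    except RuntimeError as exc:
        raise FitError(f"double fit did not converge: {exc}") from exc
    a1, k1, a2, k2 = (float(v) for v in popt)
    var1, var2 = float(pcov[1, 1]), float(pcov[3, 3])
    if k1 < k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
        var1, var2 = var2, var1
    resid = hist.counts - _double_pdf(hist.centers, a1, k1, a2, k2)
    sse = float(np.sum(resid**2))
    tot = a1 + a2
    cis = tuple(
        (max(k - 1.96 * math.sqrt(max(v, 0.0)), 0.0), k + 1.96 * math.sqrt(max(v, 0.0)))
        for k, v in ((k1, var1), (k2, var2))
    )
    return RateFit(
        model="double",
        rates=(k1, k2),
        amplitudes=(a1, a2),
        weights=(a1 / tot, a2 / tot) if tot > 0 else (0.5, 0.5),
        ci95=cis,
        n=hist.n_total,
        sse=sse,
        bic=_bic(sse, len(hist.counts), 4),
        degenerate=(k1 / k2 < DEGENERACY_RATIO) if k2 > 0 else True,
    )


def mle_rate(dwells: Sequence[float]) -> float:
    """Exact exponential maximum-likelihood rate: ``1 / mean(dwell)``."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell set")
    if np.any(d <= 0):
        raise ValueError("dwell times must be positive")
    return float(1.0 / d.mean())


def bootstrap_ci(
    dwells: Sequence[float],
    fit_fn: Callable[[LogDwellHistogram], RateFit] | None = None,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    n_bins: int = 30,
) -> tuple[tuple[float, float], ...]:
    """Percentile 95% CI of the fitted rate(s) over case-resampled dwells.

    Replicates whose refit fails are skipped; more than 10% skipped
    raises :class:`FitError`.
    """
    if B < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    fit_fn = fit_fn or fit_mono_loghist
    rng = rng if rng is not None else np.random.default_rng()
    d = np.asarray(dwells, dtype=float)
    samples: list[tuple[float, ...]] = []
    skipped = 0
    for _ in range(B):
        res = d[rng.integers(0, len(d), len(d))]
        try:
            fit = fit_fn(build_loghist(res, n_bins))
        except (FitError, ValueError):
            skipped += 1
            continue
        samples.append(fit.rates)
    if skipped > 0.1 * B:
        raise FitError(f"bootstrap unstable: {skipped}/{B} replicates failed")
    arr = np.array(samples)
    return tuple(
        (float(np.percentile(arr[:, j], 2.5)), float(np.percentile(arr[:, j], 97.5)))
        for j in range(arr.shape[1])
    )


def select_model(mono_fit: RateFit, double_fit: RateFit) -> str:
    """``"double"`` iff it improves BIC and its components are resolvable."""
    if double_fit.degenerate:
        return "mono"
    return "double" if double_fit.bic < mono_fit.bic else "mono"
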