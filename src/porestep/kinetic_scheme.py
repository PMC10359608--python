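"""Sequential kinetic model of co-translocational unfolding.

A protein--DNA complex pulled through an alpha-hemolysin pore unfolds
through a strictly sequential chain of seven current levels.  Level ``i``
is a constant-current state whose residual current (as a percentage of the
open-pore current) fingerprints the partially unfolded intermediate, and
the irreversible step ``i -> i+1`` that leaves it has an exponential dwell
time with rate ``k_i`` (s^-1).  The last step, ``7 -> O``, returns the
pore to its open state.

This module encodes that model per construct (DNA attached at tyrosine 18
or tyrosine 26 of the relaxase domain) and per applied voltage, including
the wild-type two-population mixture, together with small closed-form
helpers (hypoexponential mean event duration, sliding-window net charge).

The default registry of rates and residual currents ships with the
package (``data/tables.yaml``) and can be overridden with any file of the
same structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "KineticScheme",
    "MixtureScheme",
    "RateTable",
    "load_registry",
    "scheme_for",
    "interpolate_rate",
    "hypoexp_mean",
    "window_net_charge",
]

N_LEVELS = 7

#: Integer side-chain charges at pH ~7.2 (histidine taken as neutral).
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class KineticScheme:
    """Seven-step sequential scheme for one construct at one voltage.

    ``step_rates[i]`` is the rate (s^-1) of the step leaving level ``i+1``;
    ``level_residuals[i]`` the residual current of level ``i+1`` in percent
    of the open-pore current.  The open pore itself is 100% by definition
    and is not stored.
    """

    construct_id: str
    voltage_mv: float
    step_rates: tuple[float, ...]
    level_residuals: tuple[float, ...]
    open_pore_pa: float

    def __post_init__(self) -> None:
        if len(self.step_rates) != N_LEVELS:
            raise ValueError(f"expected {N_LEVELS} step rates, got {len(self.step_rates)}")
        if len(self.level_residuals) != N_LEVELS:
            raise ValueError(
                f"expected {N_LEVELS} level residuals, got {len(self.level_residuals)}"
            )
        if any(k <= 0 for k in self.step_rates):
            raise ValueError("all step rates must be positive")
        if any(not 0.0 < r < 100.0 for r in self.level_residuals):
            raise ValueError("level residuals must lie in (0, 100) percent")
        if self.open_pore_pa <= 0:
            raise ValueError("open-pore current must be positive")

    @property
    def level_currents_pa(self) -> tuple[float, ...]:
        """Absolute level currents in pA."""
        return tuple(r / 100.0 * self.open_pore_pa for r in self.level_residuals)


@dataclass(frozen=True)
class MixtureScheme:
    """Weighted mixture of kinetic schemes sharing voltage and open pore.

    Models a wild-type sample in which single molecules belong to one of
    two populations (DNA bound at Y18 or at Y26).
    """

    components: tuple[KineticScheme, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise ValueError("components and weights must have equal length")
        if not self.components:
            raise ValueError("mixture needs at least one component")
        if any(w < 0 or w > 1 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        v0, io0 = self.components[0].voltage_mv, self.components[0].open_pore_pa
        for c in self.components[1:]:
            if c.voltage_mv != v0 or c.open_pore_pa != io0:
                raise ValueError("mixture components must share voltage and open-pore current")

    @property
    def voltage_mv(self) -> float:
        return self.components[0].voltage_mv

    @property
    def open_pore_pa(self) -> float:
        return self.components[0].open_pore_pa


@dataclass(frozen=True)
class _StepAnchors:
    """Printed (voltage, rate) anchors for one step of one construct."""

    rates: tuple[tuple[float, float], ...]  # sorted (voltage_mv, rate)
    ci95: Mapping[float, tuple[float, float]]
    voltage_dependent: bool

    def rate_at_anchor(self, voltage_mv: float) -> float | None:
        for v, k in self.rates:
            if v == voltage_mv:
                return k
        return None


@dataclass(frozen=True)
class RateTable:
    """Registry of per-construct step-rate anchors and level residuals."""

    steps: Mapping[str, tuple[_StepAnchors, ...]]  # construct -> 7 steps
    residuals: Mapping[str, tuple[float, ...]]
    residual_sds: Mapping[str, tuple[float, ...]]
    open_pore_anchor: tuple[float, float]  # (voltage_mv, current_pa)
    voltage_range_mv: tuple[float, float]
    capture_anchors: tuple[tuple[float, float], ...]  # (voltage_mv, events/min)
    wt_weights: Mapping[str, float]
    gdnhcl_blockades: Mapping[str, tuple[float, float]]
    wt_observed: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    @property
    def constructs(self) -> tuple[str, ...]:
        return tuple(self.steps)

    def open_pore_pa(self, voltage_mv: float) -> float:
        """Open-pore current, scaled ohmically from the printed anchor."""
        v0, i0 = self.open_pore_anchor
        return i0 * voltage_mv / v0

    def capture_rate_per_min(self, voltage_mv: float) -> float:
        """Capture frequency, linear between the printed endpoints."""
        anchors = sorted(self.capture_anchors)
        (v1, f1), (v2, f2) = anchors[0], anchors[-1]
        if not v1 <= voltage_mv <= v2:
            raise ValueError(f"voltage {voltage_mv} mV outside capture anchors [{v1}, {v2}]")
        if v2 == v1:
            return f1
        return f1 + (f2 - f1) * (voltage_mv - v1) / (v2 - v1)


def _default_registry_text() -> str:
    return resources.files("porestep").joinpath("data/tables.yaml").read_text()


def load_registry(path: str | Path | None = None) -> RateTable:
    """Load a rate registry; with no argument, the packaged default tables."""
    text = Path(path).read_text() if path is not None else _default_registry_text()
    raw = yaml.safe_load(text)
    lo, hi = raw["voltage_range_mv"]
    steps: dict[str, tuple[_StepAnchors, ...]] = {}
    residuals: dict[str, tuple[float, ...]] = {}
    residual_sds: dict[str, tuple[float, ...]] = {}
    for cid, cfg in raw["constructs"].items():
        anchors = []
        for i in range(1, N_LEVELS + 1):
            scfg = cfg["steps"][str(i)]
            rates = tuple(sorted((float(v), float(k)) for v, k in scfg["rates"].items()))
            for v, k in rates:
                if not lo <= v <= hi:
                    raise ValueError(f"anchor voltage {v} outside [{lo}, {hi}]")
                if k <= 0:
                    raise ValueError("anchor rates must be positive")
            ci = {float(v): (float(a), float(b)) for v, (a, b) in scfg.get("ci95", {}).items()}
            anchors.append(
                _StepAnchors(rates, ci, bool(scfg.get("voltage_dependent", False)))
            )
        steps[cid] = tuple(anchors)
        residuals[cid] = tuple(float(r) for r in cfg["level_residual_pct"])
        residual_sds[cid] = tuple(float(r) for r in cfg.get("level_residual_sd_pct", ()))
    op = raw["open_pore"]
    blk = raw["gdnhcl_blockades"]
    return RateTable(
        steps=steps,
        residuals=residuals,
        residual_sds=residual_sds,
        open_pore_anchor=(float(op["anchor_voltage_mv"]), float(op["anchor_current_pa"])),
        voltage_range_mv=(float(lo), float(hi)),
        capture_anchors=tuple(
            sorted((float(v), float(f)) for v, f in raw["capture_rate_per_min"].items())
        ),
        wt_weights={k: float(v) for k, v in raw["wt_mixture_weights"].items()},
        gdnhcl_blockades={k: tuple(float(x) for x in v) for k, v in blk.items()},
        wt_observed=raw.get("wt_observed_rates", {}),
    )


_DEFAULT_REGISTRY: RateTable | None = None


def default_registry() -> RateTable:
    """The packaged registry, loaded once."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def interpolate_rate(
    step: int,
    construct_id: str,
    voltage_mv: float,
    registry: RateTable | None = None,
) -> float:
    """Rate of ``step`` (1-based: step ``i`` leaves level ``i``) at a voltage.

    Voltage-dependent steps with at least two printed anchors are
    interpolated log-linearly (geometrically) between the nearest anchors,
    the usual behaviour when barrier-crossing rates vary exponentially
    with voltage; an anchor voltage returns the printed value exactly.
    Steps without a significant voltage dependence (or with a single
    anchor) return their +120 mV value throughout the supported range.
    """
    reg = registry or default_registry()
    if construct_id not in reg.steps:
        raise ValueError(f"unknown construct {construct_id!r}")
    if not 1 <= step <= N_LEVELS:
        raise ValueError(f"step must be in 1..{N_LEVELS}")
    anchors = reg.steps[construct_id][step - 1]
    exact = anchors.rate_at_anchor(voltage_mv)
    if exact is not None:
        return exact
    if not anchors.voltage_dependent or len(anchors.rates) < 2:
        # flat in voltage: single printed value applies
        lo, hi = reg.voltage_range_mv
        if not lo <= voltage_mv <= hi:
            raise ValueError(f"voltage {voltage_mv} mV outside supported [{lo}, {hi}]")
        return anchors.rates[0][1]
    volts = [v for v, _ in anchors.rates]
    if not volts[0] <= voltage_mv <= volts[-1]:
        raise ValueError(
            f"voltage {voltage_mv} mV outside anchor range [{volts[0]}, {volts[-1]}]"
        )
    for (v1, k1), (v2, k2) in zip(anchors.rates, anchors.rates[1:]):
        if v1 <= voltage_mv <= v2:
            frac = (voltage_mv - v1) / (v2 - v1)
            return math.exp(math.log(k1) + frac * (math.log(k2) - math.log(k1)))
    raise AssertionError("unreachable")


def scheme_for(
    construct_id: str,
    voltage_mv: float,
    registry: RateTable | None = None,
) -> KineticScheme | MixtureScheme:
    """Kinetic scheme for a construct at a voltage in the supported range.

    ``"wt"`` returns the two-population :class:`MixtureScheme` of the Y18
    and Y26 schemes with the registry's default weights (0.78 / 0.22, the
    published population split; override the registry to change them).
    """
    reg = registry or default_registry()
    lo, hi = reg.voltage_range_mv
    if not lo <= voltage_mv <= hi:
        raise ValueError(f"voltage {voltage_mv} mV outside supported range [{lo}, {hi}]")
    if construct_id == "wt":
        comps = []
        weights = []
        for cid, w in reg.wt_weights.items():
            comps.append(scheme_for(cid, voltage_mv, reg))
            weights.append(w)
        return MixtureScheme(tuple(comps), tuple(weights))
    if construct_id not in reg.steps:
        raise ValueError(f"unknown construct {construct_id!r}")
    rates = tuple(
        interpolate_rate(i, construct_id, voltage_mv, reg) for i in range(1, N_LEVELS + 1)
    )
    return KineticScheme(
        construct_id=construct_id,
        voltage_mv=voltage_mv,
        step_rates=rates,
        level_residuals=reg.residuals[construct_id],
        open_pore_pa=reg.open_pore_pa(voltage_mv),
    )


def hypoexp_mean(scheme: KineticScheme) -> float:
    """Mean whole-event duration, sum of per-step mean dwells (seconds).

    The total duration of a strictly sequential event is hypoexponential,
    with mean ``sum(1 / k_i)``.
    """
    return sum(1.0 / k for k in scheme.step_rates)


def window_net_charge(
    protein_sequence: str, window_length: int
) -> list[tuple[int, int]]:
    """Sliding-window net side-chain charge along a protein sequence.

    Windows are half-open ``[i, i + window_length)`` on the 0-based
    sequence; D/E count -1, K/R count +1, histidine and all other residues
    0 (integer charges at neutral pH, no pKa refinement).  Used to ask
    whether the first segment threaded into the pore is net negative and
    hence assisted by the applied field.
    """
    seq = protein_sequence.upper()
    bad = set(seq) - _AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    if not 1 <= window_length <= len(seq):
        raise ValueError("window_length must be in [1, len(sequence)]")
    charges = [RESIDUE_CHARGE.get(aa, 0) for aa in seq]
    out = []
    total = sum(charges[:window_length])
    out.append((0, total))
    for i in range(1, len(seq) - window_length + 1):
        total += charges[i + window_length - 1] - charges[i - 1]
        out.append((i, total))
    return out
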