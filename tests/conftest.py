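import numpy as np
import pytest

from porestep import (
    TraceParams,
    default_registry,
    draw_event,
    render_single_event,
    scheme_for,
)
from porestep.segmentation import (
    assign_ordinals,
    detect_events,
    extract_dwell_table,
    idealize_event,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def y18():
    return scheme_for("Y18", 120)


@pytest.fixture(scope="session")
def y26():
    return scheme_for("Y26", 120)


@pytest.fixture(scope="session")
def wt():
    return scheme_for("wt", 120)


@pytest.fixture(scope="session")
def segmented_y18(y18):
    """300 noisy (sd 2 pA, unfiltered) rendered + segmented Y18 events.

    Shared by the recovery-rate and dwell-accuracy tests; returns the
    event plans, the idealizations and the dwell table.
    """
    rng = np.random.default_rng(91)
    params = TraceParams(noise_sd_pa=2.0, filter_cutoff_hz=None, open_pore_pa=y18.open_pore_pa)
    plans, ideals = [], []
    for i in range(300):
        plan = draw_event(y18, rng)
        plans.append(plan)
        trace = render_single_event(plan, params, rng)
        a, b = max(detect_events(trace), key=lambda w: w[1] - w[0])
        calls = idealize_event(trace.samples[a:b], 20000.0, offset_s=a / 20000.0)
        ideals.append(assign_ordinals(calls, y18.level_residuals, y18.open_pore_pa, i))
    table = extract_dwell_table(ideals)
    return plans, ideals, table
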