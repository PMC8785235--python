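import numpy as np
import pytest

from larvaphen import schedules
from larvaphen.trace_model import AssaySession, LocomotionTrace, ZoneTrace


def make_trace(
    distances,
    *,
    subject_id="s1",
    condition="control",
    bin_width=1.0,
    t0=0.0,
    well_id="A1",
):
    return LocomotionTrace(
        subject_id=subject_id,
        well_id=well_id,
        condition=condition,
        bin_width=bin_width,
        t0=t0,
        distances=np.asarray(distances, dtype=float),
    )


def make_fld_session(traces):
    return AssaySession(
        kind="fld", traces=traces, regime=schedules.regime_preset("fld_default")
    )


def make_startle_session(traces):
    return AssaySession(
        kind="startle",
        traces=traces,
        regime=schedules.regime_preset("startle_default"),
        stimuli=schedules.stimulus_preset(),
    )


def make_zone_trace(social, middle, far, *, subject_id="s1", condition="control",
                    bin_width=900.0):
    return ZoneTrace(
        subject_id=subject_id,
        condition=condition,
        bin_width=bin_width,
        t0=0.0,
        zones={
            "social": np.asarray(social, float),
            "middle": np.asarray(middle, float),
            "far": np.asarray(far, float),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220413)
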