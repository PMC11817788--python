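import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ictal import SimConfig, Session, ContinuousSignal, EventSeries, SeizureAnnotation
from ictal import generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def annotation():
    return SeizureAnnotation(
        stim_on_s=100.0, stim_off_s=102.0, end_ipsi_s=110.0, end_contra_s=112.0
    )


@pytest.fixture()
def tiny_session(annotation):
    """Small hand-built session: one 1 Hz signal, sounds and licks."""
    rng = np.random.default_rng(0)
    sig = ContinuousSignal(
        name="ofc_lfp", samples=rng.standard_normal(250), rate_hz=1.0, units="uV"
    )
    return Session(
        session_id="tiny",
        signals={"ofc_lfp": sig},
        events={
            "sound": EventSeries(name="sound", times_s=np.array([50.0, 105.0, 120.0])),
            "lick": EventSeries(name="lick", times_s=np.array([50.3, 50.4, 121.5])),
        },
        annotation=annotation,
        meta={"animal_id": "m0"},
    )


@pytest.fixture(scope="session")
def lean_session():
    """One generated session with LFP + photometry (no MUA, for speed)."""
    cfg = SimConfig(seed=42, signals=("ofc_lfp", "hc_ipsi", "hc_contra", "photo", "wheel"))
    return generate_session(cfg)
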