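import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


from coughval import synthetic_data as sd  # noqa: E402


NOISELESS_DETECTOR = sd.DetectorParams(
    p_detect_cough=1.0,
    p_detect_other=0.0,
    spurious_rate=0.0,
    p_log_missed_cough=0.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Three default-parameter sessions, one phone."""
    params = sd.SimulatorParams(seed=42, n_sessions=3, devices=("phone1",))
    return sd.simulate_cohort(params)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Perfect detector and annotators: the noiseless limit."""
    params = sd.SimulatorParams(
        seed=7,
        n_sessions=2,
        devices=("phone1",),
        detector=NOISELESS_DETECTOR,
        annotators=(sd.PERFECT_ANNOTATOR,) * 3,
    )
    return sd.simulate_cohort(params)
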