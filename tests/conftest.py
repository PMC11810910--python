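"""Shared fixtures: miniature simulated experiments built at session scope."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pareidoscope as ps
from pareidoscope.pipeline import ExperimentConfig, ObserverConfig, simulate_participant

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fx_tiny():
    """Default-observer tiny experiment: 3 participants x 3 sessions, 1/10 scale."""
    return ps.make_fixtures("tiny", seed=1)


@pytest.fixture(scope="session")
def fx_tiny_random():
    """Random observer (beta=0, no lapse/bias): choices carry no pixel signal."""
    return ps.make_fixtures(
        "tiny", seed=2,
        observer_overrides={"beta": 0.0, "lapse": 0.0, "position_bias_sd": 0.0},
    )


@pytest.fixture(scope="session")
def template_run():
    """A deterministic template observer (beta=50, lapse=0) run at tiny scale:
    one participant, 100 sessions -> 1,200 test trials."""
    cfg = ExperimentConfig(
        categories=("human_face",), n_sessions=100, participants=("S01",),
        geometry_scale=0.1, seed=1,
        observer=ObserverConfig(beta=50.0, lapse=0.0),
    )
    log, store = simulate_participant(cfg, "human_face", "S01")
    ds = ps.build_choice_dataset(log, store)
    template = ps.make_observer(cfg, "human_face", "S01", store).template
    return {"config": cfg, "log": log, "store": store, "ds": ds, "template": template}


@pytest.fixture(scope="session")
def interior_vc_dataset():
    """Synthetic choice dataset with genuine per-trial and per-participant
    luminance offsets (shared by all three planes of a trial), so the mixed
    model's variance components are interior rather than on the boundary."""
    rng = np.random.default_rng(42)
    n_part, n_per = 4, 30
    n = n_part * n_per
    h, w = 12, 10
    base = rng.normal(128, 30, size=(n, 3, h, w))
    trial_off = rng.normal(0, 12, size=(n, 1, 1, 1))
    part = np.repeat([f"S{i + 1}" for i in range(n_part)], n_per).astype(object)
    part_off = rng.normal(0, 8, size=n_part)[np.repeat(np.arange(n_part), n_per)]
    pixels = np.clip(
        np.round(base + trial_off + part_off[:, None, None, None]), 0, 255
    ).astype(np.uint8)
    ds = ps.ChoiceDataset(
        stimuli=pixels, chosen_idx=rng.integers(0, 3, n), participant=part,
        trial=np.arange(n), rt_ms=np.full(n, 800.0), category="human_face",
    )
    return ds, ps.AOISpec(0, 0, w, h)
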