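import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phmri import (
    Atlas,
    BoldSession,
    RegionResponse,
    ResponseSpec,
    SessionConfig,
    generate_atlas,
    generate_session,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_atlas() -> Atlas:
    """Reduced desk-scale atlas: 6 separated block regions on a 24x24x12 grid."""
    return generate_atlas((24, 24, 12), n_regions=6, seed=7)


@pytest.fixture(scope="session")
def short_cfg() -> SessionConfig:
    """Shortest admissible session (60 acquisitions) for cheap unit tests."""
    return SessionConfig(shape=(24, 24, 12), n_acquisitions=60, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def full_cfg() -> SessionConfig:
    """Full-length (500 acquisition) noiseless session config on the small grid."""
    return SessionConfig(shape=(24, 24, 12), n_acquisitions=500, noise_sd=0.0, seed=1)


def make_session(
    atlas: Atlas,
    cfg: SessionConfig,
    responses: dict[int, RegionResponse] | None = None,
    treatment: str = "drug",
    **cfg_overrides,
) -> BoldSession:
    """Session with the given per-region responses under one treatment."""
    import dataclasses

    if cfg_overrides:
        cfg = dataclasses.replace(cfg, **cfg_overrides)
    spec = ResponseSpec({(treatment, rid): r for rid, r in (responses or {}).items()})
    return generate_session(atlas, spec, cfg, treatment)


@pytest.fixture(scope="session")
def null_session(small_atlas, full_cfg) -> BoldSession:
    """Noiseless, driftless, response-free 500-acquisition session."""
    return make_session(small_atlas, full_cfg, None, treatment="vehicle")
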