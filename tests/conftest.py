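"""Shared fixtures: moderate-size ray traces reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from rotorscan import MicroscopeConfig, trace_depth_response


@pytest.fixture(scope="session")
def paper_config() -> MicroscopeConfig:
    """20x dry NA 0.75, 56.6 µm pinhole, #1.5H coverslip, aqueous sample."""
    return MicroscopeConfig()


@pytest.fixture(scope="session")
def matched_config(paper_config) -> MicroscopeConfig:
    return paper_config.replace(design_aberration_free=True)


@pytest.fixture(scope="session")
def dr_water(paper_config):
    """Depth response for the aqueous sample, z_F 0–40 µm (plus the K-estimation
    depths), shared across tests to keep the suite fast."""
    z_f = np.unique(np.concatenate([np.arange(0.0, 41.0, 1.0), [5.0, 7.0]]))
    return trace_depth_response(paper_config, z_f_grid=z_f, n_rays=150_000, seed=101)


@pytest.fixture(scope="session")
def dr_matched(matched_config):
    """Index-matched depth response, z_F 0–50 µm in 1 µm steps."""
    z_f = np.arange(0.0, 51.0, 1.0)
    return trace_depth_response(matched_config, z_f_grid=z_f, n_rays=100_000, seed=202)
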