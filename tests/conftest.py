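"""Shared fixtures: small synthetic studies and ground truths.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from swimsyn.config import PipelineConfig
from swimsyn.synth import make_ground_truth, make_study


@pytest.fixture(scope="session")
def truth10x3():
    """Canonical 10-muscle, 3-synergy ground truth."""
    return make_ground_truth(10, 3, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    """2-per-group configuration with light stochastic settings for speed."""
    cfg = PipelineConfig(seed=5)
    cfg.synth.n_per_group = 2
    cfg.synergy.n_restarts = 8
    cfg.cluster.n_repeats = 50
    cfg.cluster.gap_b = 20
    cfg.cluster.gap_ref_repeats = 4
    cfg.cluster.k_max = 4
    return cfg


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """2-per-group synthetic study (8 recordings)."""
    return make_study(small_cfg.synth, small_cfg.seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
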