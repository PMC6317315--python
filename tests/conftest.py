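"""Shared fixtures: one full pipeline run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from rubychip import (
    PipelineConfig,
    demo_genome_spec,
    make_genome,
    run_pipeline,
)

SEED = 0  # canonical fixture seed for the whole suite


@pytest.fixture(scope="session")
def genome():
    return make_genome(demo_genome_spec(SEED))


@pytest.fixture(scope="session")
def demo_result():
    """Full end-to-end run on the bundled four-factor study."""
    return run_pipeline(PipelineConfig(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
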