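"""Shared fixtures: evolved cohorts are expensive, so they are session-scoped."""

from __future__ import annotations

import pytest

from teflow.evolution import EvolutionConfig, evolve

# Frozen study conditions for the cohort-level checks: scaled-down replicate
# count/generations relative to the original 100 x 10,000 experiment.
MD_COHORT_SEED = 101
SL_COHORT_SEED = 202


@pytest.fixture(scope="session")
def evolved_cohorts() -> dict:
    """20 GA replicates per task (pop 100, <=2000 generations each)."""
    cfg = EvolutionConfig()
    return {
        "md": evolve("md", cfg, seed=MD_COHORT_SEED),
        "sl": evolve("sl", cfg, seed=SL_COHORT_SEED),
    }
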