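"""Shared fixtures: one small synthetic cohort and one full pipeline run,
both session-scoped (simulation and pipeline are deterministic under seed)."""

from __future__ import annotations

import pytest

from hiddenvar import PipelineConfig
from hiddenvar.pipeline import inputs_from_cohort, run_pipeline
from hiddenvar.synthio import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=11, n_donors=10, n_insertions=8, coverage=2.0)


@pytest.fixture(scope="session")
def cohort(sim_cfg, tmp_path_factory):
    return simulate_cohort(sim_cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def pipeline_run(cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(PipelineConfig(seed=11), inputs_from_cohort(cohort),
                          outdir)
    return report, outdir
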