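from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from kinefuse.pipeline import run_all
from kinefuse.simulate import default_scenario, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The reference synthetic cohort (20 tumours, 10 normals, 14 planted
    fusions) generated once per session."""
    outdir = tmp_path_factory.mktemp("scenario")
    return simulate_cohort(default_scenario(seed=SCENARIO_SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_result(scenario, tmp_path_factory):
    """Full pipeline run over the reference cohort."""
    outdir = tmp_path_factory.mktemp("pipeline")
    p = scenario.paths
    return run_all(p["sample_sheet"], p["gtf"], p["registry"], p["fasta"],
                   p["expression"], p["normals_dir"], outdir)
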