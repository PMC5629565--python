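import pytest

from splicescout.pipeline import PipelineConfig, run_analytic_data
from splicescout.simulate import SimScenario, simulate


@pytest.fixture(scope="session")
def sim_data():
    """Default synthetic scenario: ten 3-exon genes, 20 planted novel
    junctions, 3 error-free spanning reads per truth."""
    return simulate(SimScenario(seed=11))


@pytest.fixture(scope="session")
def sim_result(sim_data):
    """Full analytic pipeline run on the default scenario."""
    return run_analytic_data(sim_data.genome, sim_data.reads, sim_data.genes, PipelineConfig())


def truth_recovered(calls, truth, buffer=5):
    """Is some call within ``buffer`` of the truth on both boundaries?"""
    return any(
        c.chrom == truth.chrom
        and abs(c.left_end - truth.left_end) <= buffer
        and abs(c.right_start - truth.right_start) <= buffer
        for c in calls
    )
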