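import numpy as np
import pytest

from scnanopipe import pipeline, simulator


@pytest.fixture(scope="session")
def noiseless_run():
    """Error-free synthetic experiment plus the full pipeline result."""
    cfg = simulator.SimConfig(seed=7)
    sim = simulator.simulate_experiment(cfg)
    result = pipeline.run_pipeline(
        sim.reads, sim.truth.read_alignments, sim.genes, sim.genome,
        pipeline.PipelineConfig(min_genes=10),
    )
    return sim, result


@pytest.fixture(scope="session")
def noisy_run():
    """Synthetic experiment with nanopore-like error rates plus pipeline result."""
    cfg = simulator.SimConfig(
        seed=11, barcode_sub=0.01, barcode_indel=0.005,
        body_sub=0.02, body_indel=0.01,
    )
    sim = simulator.simulate_experiment(cfg)
    result = pipeline.run_pipeline(
        sim.reads, sim.truth.read_alignments, sim.genes, sim.genome,
        pipeline.PipelineConfig(min_genes=10),
    )
    return sim, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
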