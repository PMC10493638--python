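import pytest

from triadkit import simulate as sim


SMALL_CONFIG = dict(
    seed=7,
    n_chromosomes_per_haplotype=3,
    chrom_length=200_000,
    n_triads=12,
    n_pairs=3,
    n_singletons=3,
    nlr=sim.NLRConfig(n_genic=3, n_intergenic=3),
)


@pytest.fixture(scope="session")
def small_sim():
    """One small deterministic triploid simulation shared by the suite."""
    cfg = sim.SimulationConfig(**SMALL_CONFIG)
    genomes, models, hits, truth = sim.simulate_triploid(cfg)
    counts = sim.simulate_expression(truth, cfg)
    return cfg, genomes, models, hits, truth, counts
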