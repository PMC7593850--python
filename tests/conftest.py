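import numpy as np
import pytest

from picomethyl import pipeline, simulate


def small_config(seed: int = 7) -> simulate.SimulationConfig:
    """A miniature experiment: 20 kb genome, two days, both arms, small
    planted effects — fast enough for per-test end-to-end runs."""
    return simulate.SimulationConfig(
        seed=seed,
        contig_lengths=(12_000, 8_000),
        n_genes=8,
        gene_length_range=(400, 1200),
        days=(4, 10),
        effects=[
            simulate.EffectSpec(
                name="starvation_hypo", n_sites=40, delta_range=(0.15, 0.36),
                direction="hypo", truth_range=(0.5, 0.95), ramp=True,
            ),
            simulate.EffectSpec(
                name="aza_day4_hypo", n_sites=25, delta_range=(0.15, 0.30),
                direction="hypo", days=[4], treatments=["5AZA"],
                truth_range=(0.5, 0.95),
            ),
            simulate.EffectSpec(
                name="aza_day10_hyper", n_sites=30, delta_range=(0.15, 0.30),
                direction="hyper", days=[10], treatments=["5AZA"],
                truth_range=(0.0, 0.6),
            ),
        ],
    )


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_experiment(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("exp")
    simulate.simulate_experiment(small_cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def small_loaded(small_experiment):
    return pipeline.load_experiment(small_experiment)


def random_genome(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = list("ACGTN") if with_n else list("ACGT")
    p = [0.28, 0.22, 0.22, 0.26, 0.02] if with_n else [0.28, 0.22, 0.22, 0.28]
    return "".join(rng.choice(alphabet, size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
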