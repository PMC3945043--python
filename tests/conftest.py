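import pytest

from nascentscan.simulate import SimulationConfig, simulate


def small_config(seed: int = 3, **kwargs) -> SimulationConfig:
    """A 2-Mb genome with a few elements of every kind; fast to simulate."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"chrS1": 2_000_000},
        n_genes=30,
        n_lncrna=3,
        n_divergent=3,
        n_antisense=3,
        n_repeat=2,
        n_other_genic=2,
        n_intergenic=4,
        n_erna_pairs=6,
        n_non_pol2=8,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    paths = small_sim.write(outdir)
    return {k: str(v) for k, v in paths.items()}
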