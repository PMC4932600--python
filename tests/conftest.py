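import pytest

from homeocall import (
    SimConfig,
    make_worked_fixture,
    run_pipeline,
    simulate_allopolyploid,
)


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """The hand-traceable 1-gene / 2-HSP / 6-read dataset."""
    return make_worked_fixture(str(tmp_path_factory.mktemp("worked")))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small noisy allotetraploid simulation shared across tests."""
    cfg = SimConfig(n_genes=12, gene_length=700, seed=11, coverage=25.0)
    out = simulate_allopolyploid(cfg, str(tmp_path_factory.mktemp("sim")))
    return cfg, out


@pytest.fixture(scope="session")
def small_sim_calls(small_sim):
    """Pipeline output on the shared simulation, both diploids present."""
    _, res = small_sim
    calls, report = run_pipeline(
        res.paths["sam"],
        res.paths["hsp_vcf"],
        res.paths["gff"],
        res.sbs_paths,
        polyploid_coverage=res.paths["polyploid_coverage"],
        diploid_coverage=res.diploid_coverage_paths,
    )
    return calls, report
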