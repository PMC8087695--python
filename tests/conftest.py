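import pytest

from haplotab import simdip
from haplotab.ioformats import SV_CATEGORIES


@pytest.fixture(scope="session")
def small_config() -> simdip.SimConfig:
    return simdip.SimConfig(
        n_chromosomes=1, chrom_length=300_000, n_genes=80, seed=5,
        sv_counts={c: 2 for c in SV_CATEGORIES}, sv_size_range=(50, 2000),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> simdip.SimBundle:
    """One 300 kb chromosome, 80 genes, 2 SVs per category."""
    return simdip.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default-scale pipeline run (3 x 1 Mb, 1000 genes, seed 42)."""
    from haplotab import pipeline

    cfg = pipeline.PipelineConfig()
    cfg.sim.seed = 42
    outdir = tmp_path_factory.mktemp("default_run")
    report = pipeline.run_pipeline(cfg, outdir)
    return report, outdir
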