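import numpy as np
import pytest

from flaxnue import pheno, popgen, synth
from flaxnue.workflow_io import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_geno():
    """150 inbred accessions, 3 chromosomes, ~900 polymorphic markers."""
    spec = synth.GenomeSpec(n_chromosomes=3, n_markers_per_chrom=300,
                            n_accessions=150, seed=1)
    return synth.simulate_genotypes(spec)


@pytest.fixture(scope="session")
def medium_geno():
    """300 accessions for parameter-recovery checks."""
    spec = synth.GenomeSpec(n_chromosomes=3, n_markers_per_chrom=250,
                            n_accessions=300, seed=10)
    return synth.simulate_genotypes(spec)


@pytest.fixture(scope="session")
def medium_grm(medium_geno):
    return popgen.vanraden_grm(medium_geno).to_numpy()


@pytest.fixture(scope="session")
def small_traits(small_geno):
    plan = synth.default_qtl_plan(small_geno, seed=2)
    raw = synth.simulate_phenotypes(small_geno, plan, n_reps=3, seed=3)
    return pheno.derive_traits(pheno.compute_blues(raw))


@pytest.fixture(scope="session")
def pipeline_result():
    """One deterministic end-to-end run on the bundled small configuration
    (150 accessions, 3 chromosomes, 3000 markers), shared across tests."""
    cfg = RunConfig(seed=1, n_accessions=150, n_chromosomes=3,
                    n_markers_per_chrom=1000, n_genes=1500,
                    gs_repeats=20, m1_size=1000)
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
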