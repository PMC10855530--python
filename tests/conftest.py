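import numpy as np
import pytest
from importlib import resources

from mitocompare import read_gene_table
from mitocompare.synthetic import SimulationSpec, simulate_family


@pytest.fixture(scope="session")
def taeniops_table():
    """Packaged gene table of the African hind study genome (printed-table
    layout, 38 annotated features, 16,572 bp)."""
    path = resources.files("mitocompare.data") / "cephalopholis_taeniops_oq420715_genes.tsv"
    return read_gene_table(path)


@pytest.fixture(scope="session")
def small_family():
    """A 6-taxon simulated family with defaults scaled down, reused by the
    pipeline-level tests."""
    spec = SimulationSpec(seed=11, n_taxa=6, cr_repeat_taxon="taxon02",
                          rearrangements=(("taxon06", ("trnD", "CR")),))
    return simulate_family(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
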