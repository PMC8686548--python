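import pytest

from egtcost import CellModel, CostTable, GeneRecord, GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def cost_table() -> CostTable:
    return CostTable()


@pytest.fixture
def gene() -> GeneRecord:
    """1-kb gene at 50% GC with a 300-residue product at 1000 ppm."""
    return GeneRecord(id="g1", length_bp=1000, gc=0.5, protein_length=300, abundance_ppm=1000.0)


@pytest.fixture
def yeast_like_cell() -> CellModel:
    """Small unicellular host: 1e7 proteins, 2% organellar, 100 genome copies."""
    return CellModel(
        total_proteins=1e7,
        organellar_fraction=0.02,
        c_end=100,
        import_cost=2.0,
    )


@pytest.fixture(scope="session")
def small_genome():
    """20-gene synthetic genome shared by the oracle-equivalence tests."""
    return generate_genome(GenomeSpec(n_genes=20, seed=42))


@pytest.fixture(scope="session")
def standard_genome():
    """Alphaproteobacterium-like synthetic genome (1500 genes, ~1 kb)."""
    return generate_genome(GenomeSpec(n_genes=1500, seed=1))
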