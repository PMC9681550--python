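import numpy as np
import pytest

from tsrnakit import catalog as cat
from tsrnakit import simulate as sim
from tsrnakit.reference import TRNAGene


@pytest.fixture(scope="session")
def small_reference():
    """10 synthetic tRNA genes (with a 3-copy family) plus built models."""
    genes, genome, truth = sim.simulate_trna_genes(10, seed=11)
    models = cat.build_reference_models(genes, genome)
    return {"genes": genes, "genome": genome, "truth": truth, "models": models}


@pytest.fixture(scope="session")
def classified_catalog(small_reference):
    """120 generated fragments with truth labels, already classified."""
    models = small_reference["models"]
    records, truth = sim.simulate_catalog(models, n_fragments=120, seed=13)
    cat.classify_catalog(records, models)
    return {"records": records, "truth": truth, "models": models}


@pytest.fixture()
def handmade_gene():
    """A hand-built intronless 72-nt plus-strand gene with known sequence."""
    rng = np.random.default_rng(5)
    body = "".join(rng.choice(list("ACGT"), size=72))
    return TRNAGene(
        gene_id="tRNA-hand-1",
        chromosome="chrT",
        start=100,
        end=172,
        strand="+",
        genomic_sequence=body,
    )
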