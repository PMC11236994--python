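import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import egranule as eg

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config():
    return eg.GenomeConfig(
        n_germline_genes=20,
        n_soma_genes=2,
        n_structural={"rRNA": 2, "tRNA": 1, "snRNA": 1, "snoRNA": 1, "ncRNA": 1},
        n_mirna=2,
        n_21u=2,
        gene_length_range=(150, 250),
        chrom_length=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return eg.make_genome(tiny_config)


@pytest.fixture(scope="session")
def manual_genome():
    """A hand-built 5-gene genome for exact-value mapping/counting tests.

    gene C duplicates gene A's sequence so that reads from A multi-map.
    """
    rng = np.random.default_rng(3)
    chrom = list(rng.choice(list("ACGT"), size=1200))
    chrom[650:900] = chrom[50:300]  # gene C == gene A sequence
    chrom = "".join(chrom)
    genes = [
        eg.GeneRecord("geneA", "chr1", 50, 300, "+", "germline_coding", "NEUTRAL", 1.0),
        eg.GeneRecord("geneB", "chr1", 350, 600, "-", "germline_coding", "NEUTRAL", 1.0),
        eg.GeneRecord("geneC", "chr1", 650, 900, "+", "germline_coding", "NEUTRAL", 1.0),
        eg.GeneRecord("rrna1", "chr1", 950, 1150, "+", "rRNA", "NA", 0.0),
    ]
    return eg.AnnotatedGenome({"chr1": chrom}, genes)


@pytest.fixture(scope="session")
def one_gene_genome():
    rng = np.random.default_rng(5)
    chrom = "".join(rng.choice(list("ACGT"), size=500))
    genes = [eg.GeneRecord("solo", "chr1", 100, 400, "+", "germline_coding", "E", 1.0)]
    return eg.AnnotatedGenome({"chr1": chrom}, genes)
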