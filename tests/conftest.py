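import numpy as np
import pandas as pd
import pytest

import regulonscan as rs

#: Printed regulon-table rows used as fixed references: motif string,
#: expected non-excluded matches and identity percent against the 22-nt box.
TABLE_ROWS = [
    ("Rt620_77", "CGGCTTCAAGGCGCTGAATTCG", 12, 66.7),
    ("Rt648_25", "CGGCGGATAATCCTTGATCTCG", 12, 66.7),
    ("Rt620_4", "CGAATACCAAAGCCTGATTTCG", 12, 66.7),
    ("Rt794_16", "GCGCTTCGTGGCGTGGATTTCG", 12, 66.7),
    ("Rt794_99", "CGGATTCCAGTAGGGATTTTCG", 13, 72.2),
    ("Rt643_15", "CGGGGTCAGCAACTGCATTTCG", 13, 72.2),
]


@pytest.fixture(scope="session")
def consensus():
    return rs.ConsensusMotif()


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic study: 120 genes, 30 true DE, planted motifs."""
    return rs.make_scenario(seed=7)


@pytest.fixture()
def tiny_genome():
    """One 2000-nt periodic contig with one gene per strand."""
    contig = ("ACGT" * 500)
    genes = [
        rs.GeneRecord("plus_gene", "c1", "+", 1000, 1600),
        rs.GeneRecord("minus_gene", "c1", "-", 201, 400),
    ]
    return rs.GenomeAnnotation(contigs={"c1": contig}, genes=genes)


def null_counts(n_genes: int, seed: int, dispersion: float = 0.05) -> rs.CountMatrix:
    """Count matrix with no true differences (for type-I checks)."""
    rng = np.random.default_rng(seed)
    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "base_mean": rng.lognormal(np.log(1000), 1.0, n_genes),
            "true_log2fc": 0.0,
            "length_nt": 900,
        }
    )
    return rs.simulate_counts(truth, 3, dispersion=dispersion, seed=seed + 1)
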