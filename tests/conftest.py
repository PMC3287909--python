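import numpy as np
import pytest

from geneburden.core import GeneRegion, GenotypeMatrix, PhenotypeVector, VariantRecord


@pytest.fixture
def small_dataset():
    """4 samples x 3 variants in one gene, built to give case counts {2, 0}
    and control counts {1, 3} under dosage counting."""
    variants = [
        VariantRecord("v1", "chr1", 110, "A", "T", maf=0.005),
        VariantRecord("v2", "chr1", 150, "A", "T", maf=0.005),
        VariantRecord("v3", "chr1", 190, "A", "T", maf=0.005),
    ]
    genes = [GeneRegion("G1", "chr1", 100, 200)]
    dosage = np.array([
        [1, 1, 0],  # case 1 -> 2
        [0, 0, 0],  # case 2 -> 0
        [1, 0, 0],  # control 1 -> 1
        [1, 0, 2],  # control 2 -> 3
    ], dtype=float)
    genotypes = GenotypeMatrix(["s1", "s2", "s3", "s4"], ["v1", "v2", "v3"], dosage)
    phenotype = PhenotypeVector(["s1", "s2", "s3", "s4"], np.array([1, 1, 0, 0], bool))
    return variants, genes, genotypes, phenotype
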