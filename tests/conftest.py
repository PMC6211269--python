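import numpy as np
import pytest

from epigain import GenotypeMatrix, Phenotype, SimConfig, simulate, xor_penetrance


@pytest.fixture
def toy_matrix():
    """6 samples x 3 SNPs, fully observed, both classes present."""
    geno = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 2],
            [1, 0, 0],
            [2, 2, 1],
        ],
        dtype=np.int8,
    )
    g = GenotypeMatrix(geno, ["rs1", "rs2", "rs3"], [f"s{i}" for i in range(6)])
    phen = Phenotype(np.array([0, 0, 0, 1, 1, 1]))
    return g, phen


@pytest.fixture
def xor_dataset():
    """Balanced 800-sample cohort with a planted XOR pair at columns 5 and 17."""
    cfg = SimConfig(
        n_cases=400,
        n_controls=400,
        n_snps=50,
        models=[xor_penetrance(0.4, (5, 17))],
        functional_maf=0.5,
        seed=20240101,
    )
    g, phen, truth = simulate(cfg)
    return g, phen, truth


@pytest.fixture
def parity_exact_pair():
    """16-sample two-locus parity construction with exact HWE-proportional counts.

    Both loci have genotype counts (4, 8, 4); the joint counts are exactly
    16 * P(a) * P(b) and status is parity(a + b), so the marginal tables are
    perfectly balanced: I(A;D) = I(B;D) = 0 and IG = H(D) = 1 bit.
    """
    gA, gB, y = [], [], []
    weights = {0: 1, 1: 2, 2: 1}  # 16 * (1/4, 1/2, 1/4) shares per locus
    for a in range(3):
        for b in range(3):
            for _ in range(weights[a] * weights[b]):
                gA.append(a)
                gB.append(b)
                y.append((a + b) % 2)
    return np.array(gA), np.array(gB), Phenotype(np.array(y))


@pytest.fixture
def parity_exact_trio():
    """64-sample three-locus parity construction with multinomial-proportional counts."""
    gA, gB, gC, y = [], [], [], []
    weights = {0: 1, 1: 2, 2: 1}
    for a in range(3):
        for b in range(3):
            for c in range(3):
                for _ in range(weights[a] * weights[b] * weights[c]):
                    gA.append(a)
                    gB.append(b)
                    gC.append(c)
                    y.append((a + b + c) % 2)
    return np.array(gA), np.array(gB), np.array(gC), Phenotype(np.array(y))
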