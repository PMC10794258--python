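import numpy as np
import pytest

from nestkin.genotype_io import GenotypeMatrix


def make_matrix(genotypes, depths=None, sample_ids=None, locus_ids=None):
    """Build a small GenotypeMatrix from a list-of-rows genotype spec.

    ``None`` entries mean missing; depths default to 10 everywhere.
    """
    g = np.array(
        [[(-1 if v is None else v) for v in row] for row in genotypes],
        dtype=np.int8,
    )
    n, L = g.shape
    d = np.full((n, L), 10, dtype=np.int32) if depths is None else np.asarray(depths)
    samples = sample_ids or [f"s{i + 1}" for i in range(n)]
    loci = locus_ids or [f"chr1:{j + 1}" for j in range(L)]
    return GenotypeMatrix(samples, loci, g, d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def baseline_run():
    """One filtered baseline-scenario replicate with its kinship matrix."""
    from nestkin.kinship_mds import manichaikul_kinship
    from nestkin.snp_filtering import apply_filters
    from nestkin.synthetic_data import baseline_scenario, simulate_clutches

    matrix, samples, nests, truth = simulate_clutches(baseline_scenario(seed=42))
    filtered, report = apply_filters(matrix)
    kinship = manichaikul_kinship(filtered)
    return {
        "matrix": filtered,
        "raw": matrix,
        "samples": samples,
        "nests": nests,
        "truth": truth,
        "kinship": kinship,
        "filter_report": report,
    }
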