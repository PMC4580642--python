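import numpy as np
import pytest

from epigwa.datatypes import GenotypeMatrix, SnpInfo
from epigwa.simulate import PopulationSpec, simulate_panel


def make_matrix(calls, chroms=None, positions=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = []
    for j in range(m):
        chrom = chroms[j] if chroms else "1"
        pos = positions[j] if positions else (j + 1) * 100
        snps.append(SnpInfo(id=f"{chrom}_{pos}", chromosome=chrom,
                            position=pos, maf=0.0))
    ids = [f"acc{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(ids, snps, calls)


@pytest.fixture(scope="session")
def small_panel():
    """93-accession structured panel shared across read-only tests."""
    gm, labels = simulate_panel(PopulationSpec(n_accessions=93, n_snps=300,
                                               seed=42))
    return gm, labels


@pytest.fixture(scope="session")
def vc_panel():
    """Strongly related panel for variance-component experiments.

    Separating sigma_aa^2 from sigma_e^2 needs a kinship whose Hadamard
    square is far from the identity; families of closely related
    accessions (high divergence, many small subpopulations) provide the
    informative relatedness that real inbred panels show.
    """
    gm, _ = simulate_panel(PopulationSpec(n_accessions=200, n_snps=600,
                                          n_subpops=20, fst=0.8, seed=3))
    from epigwa.kinship import compute_kinship
    G = compute_kinship(gm).values
    return G, G * G
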