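import numpy as np
import pytest

from tsplink.genotypes import GenotypeMatrix
from tsplink.recombination import RFMatrix
from tsplink.simulate import SimParams, make_true_map, shuffle_markers, simulate_population


def geno(rows, cross_type="riself", names=None):
    """Build a GenotypeMatrix from a list of call-code lists."""
    rows = np.asarray(rows, dtype=np.int8)
    m, n = rows.shape
    return GenotypeMatrix(
        marker_names=names or [f"m{i}" for i in range(m)],
        individual_ids=[f"i{j}" for j in range(n)],
        calls=rows,
        cross_type=cross_type,
    )


def rf_from_matrix(mat, names=None):
    """Wrap a plain symmetric array as an RFMatrix."""
    mat = np.asarray(mat, dtype=float)
    names = names or [f"m{i}" for i in range(len(mat))]
    return RFMatrix(names, mat, np.full(mat.shape, 100, dtype=np.int64))


def simulated_dataset(cross_type="riself", n=300, m=100, k=2, eta=0.0,
                      gamma=0.0, seed=0, shuffled=True):
    """Simulate a population and (optionally) randomise marker order."""
    sp = SimParams(n=n, m=m, k=k, cross_type=cross_type, eta=eta,
                   gamma=gamma, seed=seed)
    tm = make_true_map(sp)
    g = simulate_population(tm, sp)
    if shuffled:
        g, _ = shuffle_markers(g, seed=seed + 101)
    return tm, g


@pytest.fixture
def two_chrom_riself():
    """Clean two-chromosome RIL population, markers shuffled."""
    return simulated_dataset(m=100, k=2, seed=7)


@pytest.fixture
def line_rf():
    """rf proportional to index distance: a noiseless 'chromosome on a line'."""
    m = 8
    idx = np.arange(m)
    mat = 0.04 * np.abs(idx[:, None] - idx[None, :])
    return rf_from_matrix(mat)
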