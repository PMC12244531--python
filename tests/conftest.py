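import numpy as np
import pytest

from pericentriq.hic_io import BinTable, ContactMatrix, Region
from pericentriq import synthetic


def dense_to_matrix(dense, resolution=5000, chrom="chr1", normalization="raw",
                    weights=None, chrom_split=None):
    """Build a ContactMatrix from a dense symmetric array (test helper).

    ``chrom_split``: optional list of (name, n_bins) partitioning the rows
    into chromosomes.
    """
    dense = np.asarray(dense, dtype=float)
    n = len(dense)
    assert np.allclose(dense, dense.T)
    if chrom_split is None:
        chrom_split = [(chrom, n)]
    sizes = [(name, nb * resolution) for name, nb in chrom_split]
    bins = BinTable.from_chrom_sizes(sizes, resolution)
    iu, ju = np.triu_indices(n)
    v = dense[iu, ju]
    nz = v != 0
    return ContactMatrix(bins, iu[nz], ju[nz], v[nz],
                         normalization=normalization, weights=weights)


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.SyntheticGenomeSpec.default()


@pytest.fixture(scope="session")
def default_model():
    return synthetic.GeneratorModel()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return synthetic.ground_truth(default_spec)


@pytest.fixture(scope="session")
def arm_regions(default_spec):
    return {a.name: Region(a.name, 0, a.length) for a in default_spec.arms}


@pytest.fixture(scope="session")
def expected_maps(default_spec, default_model):
    """Deterministic expected maps for the three study conditions."""
    return {
        lam: synthetic.expected_map(default_spec, default_model, lam)
        for lam in (0.5, 1.0, 2.0)
    }


@pytest.fixture(scope="session")
def tiny_spec():
    """One 200kb arm, 40 bins at 5kb: A 60kb | B 60kb | P 80kb (right end)."""
    return synthetic.SyntheticGenomeSpec(
        arms=(
            synthetic.ArmSpec(
                "t1", 200_000, (("A", 60_000), ("B", 60_000)), 80_000, "right"
            ),
        ),
        resolution=5000,
    )


@pytest.fixture(scope="session")
def two_arm_tiny_spec():
    """Two small arms for trans-contact tests (30 + 30 bins)."""
    arm = lambda name, end: synthetic.ArmSpec(
        name, 150_000, (("A", 50_000), ("B", 50_000)), 50_000, end
    )
    return synthetic.SyntheticGenomeSpec(
        arms=(arm("tL", "right"), arm("tR", "left")), resolution=5000
    )
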