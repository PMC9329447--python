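import numpy as np
import pytest

from nbbtest import CountTable

# replicate vectors from the two worked illustrations of the gap statistic:
# separated/homogeneous vs overlapping/noisy
SEPARATED_A = np.array([4764.0, 4602.0, 4538.0])
SEPARATED_B = np.array([7877.0, 7524.0, 7871.0])
OVERLAP_A = np.array([1390.0, 1482.0, 1561.0])
OVERLAP_B = np.array([1540.0, 1270.0, 1217.0])


def make_table(counts, gene_ids, feature_ids=None, m_a=None, kind="isoform"):
    """Build a CountTable with samples A1..Am, B1..Bk."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n_samples = counts.shape[1]
    if m_a is None:
        m_a = n_samples // 2
    samples = [f"A{j}" for j in range(1, m_a + 1)] + [
        f"B{j}" for j in range(1, n_samples - m_a + 1)
    ]
    design = {s: s[0] for s in samples}
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[0])]
    return CountTable(
        np.asarray(gene_ids, dtype=object),
        np.asarray(feature_ids, dtype=object),
        counts,
        samples,
        design,
        kind,
    )


@pytest.fixture
def two_gene_table():
    counts = np.array(
        [
            [120, 100, 115, 300, 310, 290],
            [80, 95, 88, 40, 35, 50],
            [500, 480, 510, 505, 495, 500],
            [55, 60, 58, 61, 54, 57],
            [10, 12, 9, 100, 110, 95],
        ],
        dtype=float,
    )
    return make_table(counts, ["g1", "g1", "g2", "g2", "g2"],
                      ["i1", "i2", "i3", "i4", "i5"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
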