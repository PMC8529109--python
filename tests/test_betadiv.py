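"""Oracle-backed tests for the from-scratch beta-diversity statistics.

Independent oracles used here:

* brute-force Bray-Curtis and PERMANOVA sums of squares via naive loops;
* exhaustive enumeration of label splits for exact permutation p-values;
* the classical one-way ANOVA F (closed form) for univariate Euclidean
  distances;
* scikit-bio's PCoA/PERMANOVA as an external cross-check;
* orthogonal-Procrustes recovery of a Euclidean point cloud.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcstab.betadiv import (
    DistanceMatrix,
    bray_curtis,
    pcoa,
    pearson,
    permanova,
    permanova_pairwise,
)
from funcstab.errors import ContractError

from tests.conftest import abundance_frame


def brute_bray_curtis(X):
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(X[i, k] - X[j, k]) for k in range(X.shape[1]))
            den = sum(X[i, k] + X[j, k] for k in range(X.shape[1]))
            D[i, j] = num / den if den else 0.0
    return D


def brute_permanova_F(D, codes):
    """Sums-of-squares pseudo-F computed with naive double loops."""
    codes = np.asarray(codes)
    N = len(codes)
    groups = np.unique(codes)
    a = len(groups)
    ss_total = sum(D[i, j] ** 2 for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(codes == g)
        ss_within += sum(
            D[i, j] ** 2 for k, i in enumerate(idx) for j in idx[k + 1:]
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (N - a))


def euclidean_distance_matrix(points):
    points = np.asarray(points, dtype=float)
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


# -- Bray-Curtis --------------------------------------------------------------


def test_bray_curtis_identical_and_disjoint_rows():
    dist = bray_curtis(abundance_frame([[1, 2, 3], [1, 2, 3]]))
    assert dist.D[0, 1] == 0.0
    dist = bray_curtis(abundance_frame([[1, 0], [0, 1]]))
    assert dist.D[0, 1] == 1.0


def test_bray_curtis_hand_worked_case():
    """x=(0.7,0.3,0), y=(0.3,0.3,0.4): D = 0.8/2 = 0.4, similarity 60%."""
    table = abundance_frame([[0.7, 0.3, 0.0], [0.3, 0.3, 0.4]], relative=True)
    dist = bray_curtis(table, relative=False)
    assert dist.D[0, 1] == pytest.approx(0.4, abs=1e-15)
    assert dist.similarity_pct()[0, 1] == pytest.approx(60.0, abs=1e-12)


def test_bray_curtis_single_sample_rejected():
    with pytest.raises(ContractError):
        bray_curtis(abundance_frame([[1, 2]]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(min_value=0, max_value=100, allow_nan=False),
                 min_size=4, max_size=4),
        min_size=2, max_size=6,
    ).filter(lambda rows: all(sum(r) > 0 for r in rows))
)
def test_bray_curtis_matches_brute_force_and_is_bounded(rows):
    dist = bray_curtis(abundance_frame(rows), relative=False)
    expected = brute_bray_curtis(rows)
    assert np.allclose(dist.D, expected, atol=1e-12)
    assert (dist.D >= -1e-12).all() and (dist.D <= 1 + 1e-12).all()
    assert np.allclose(dist.D, dist.D.T)


# -- PCoA ---------------------------------------------------------------------


def test_pcoa_two_points_analytic():
    dist = DistanceMatrix(ids=["a", "b"], D=np.array([[0, 0.5], [0.5, 0]]))
    res = pcoa(dist)
    coords = res.coordinates.to_numpy()[:, 0]
    assert sorted(np.round(coords, 12)) == [-0.25, 0.25]
    assert (res.eigenvalues > 1e-12).sum() == 1


def test_pcoa_three_equidistant_points_split_variation_evenly():
    D = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(ids=list("abc"), D=D))
    pos = res.eigenvalues[res.eigenvalues > 1e-12]
    assert len(pos) == 2 and pos[0] == pytest.approx(pos[1], rel=1e-10)
    assert res.percent_variation[0] == pytest.approx(50.0, abs=1e-9)
    assert res.percent_variation[1] == pytest.approx(50.0, abs=1e-9)


def test_pcoa_recovers_euclidean_configuration():
    """Euclidean-recovery oracle: Procrustes RMS below 1e-8."""
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(15, 2))
    dist = DistanceMatrix(ids=[str(i) for i in range(15)],
                          D=euclidean_distance_matrix(pts))
    res = pcoa(dist, n_axes=2)
    X = res.coordinates.to_numpy()
    Y = pts - pts.mean(axis=0)
    import scipy.linalg

    R, _ = scipy.linalg.orthogonal_procrustes(X, Y)
    rms = np.sqrt(((X @ R - Y) ** 2).mean())
    assert rms < 1e-8
    assert res.eigenvalues.min() > -1e-9  # Euclidean input: no negative axes
    pos = res.percent_variation[res.eigenvalues > 0]
    assert res.percent_variation.sum() == pytest.approx(100.0, abs=1e-6)


def test_pcoa_matches_scikit_bio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    X = rng.random((8, 6))
    dist = bray_curtis(abundance_frame(X))
    ours = pcoa(dist, n_axes=3)
    theirs = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(dist.D, ids=dist.ids), number_of_dimensions=3
    )
    for j in range(3):
        a = ours.coordinates.to_numpy()[:, j]
        b = theirs.samples.to_numpy()[:, j]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_pcoa_clips_excess_axes():
    D = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(ids=list("abc"), D=D), n_axes=10)
    assert res.coordinates.shape[1] == 2


# -- PERMANOVA ----------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_distance_six():
    """Fixed 6-sample distance matrix with a mild two-group structure."""
    rng = np.random.default_rng(42)
    base = rng.random((6, 4))
    base[3:, 0] += 0.6
    return bray_curtis(abundance_frame(base)), np.array([0, 0, 0, 1, 1, 1])


def test_permanova_pseudo_F_matches_brute_force(toy_distance_six):
    dist, codes = toy_distance_six
    res = permanova(dist, codes, n_permutations=99, seed=0)
    assert res.pseudo_F == pytest.approx(brute_permanova_F(dist.D, codes), abs=1e-12)
    assert res.ss_between + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)


def test_permanova_exact_p_by_enumeration(toy_distance_six):
    """All 20 splits of 6 samples into labelled 3+3 enumerate the exact null."""
    dist, codes = toy_distance_six
    f_obs = brute_permanova_F(dist.D, codes)
    f_null = []
    for combo in combinations(range(6), 3):
        lab = np.ones(6, dtype=int)
        lab[list(combo)] = 0
        f_null.append(brute_permanova_F(dist.D, lab))
    exact_p = sum(f >= f_obs - 1e-12 for f in f_null) / len(f_null)
    res = permanova(dist, codes, n_permutations=100_000, seed=3)
    assert abs(res.p - exact_p) < 0.005


def test_permanova_univariate_equals_anova_F():
    """On Euclidean distances of 1-D data, pseudo-F is the classical F."""
    import scipy.stats

    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.normal(size=12)
        codes = np.repeat([0, 1, 2], 4)
        D = np.abs(x[:, None] - x[None, :])
        dist = DistanceMatrix(ids=[str(i) for i in range(12)], D=D / D.max())
        res = permanova(dist, codes, n_permutations=9, seed=0)
        F_classic = scipy.stats.f_oneway(*(x[codes == g] for g in range(3))).statistic
        assert res.pseudo_F == pytest.approx(F_classic, abs=1e-10)


def test_permanova_matches_scikit_bio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(21)
    X = rng.random((12, 5))
    codes = np.repeat([0, 1, 2], 4)
    dist = bray_curtis(abundance_frame(X))
    ours = permanova(dist, codes, n_permutations=99, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(dist.D, ids=dist.ids), [str(c) for c in codes],
        permutations=99,
    )
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-10)


def test_permanova_validation():
    D = np.ones((4, 4)) - np.eye(4)
    dist = DistanceMatrix(ids=list("abcd"), D=D)
    with pytest.raises(ContractError):
        permanova(dist, [0, 0, 0, 0], 9)
    with pytest.raises(ContractError):
        permanova(dist, [0, 0, 0, 1], 9)  # a group of size 1
    zero = DistanceMatrix(ids=list("abcd"), D=np.zeros((4, 4)))
    with pytest.raises(ContractError):
        permanova(zero, [0, 0, 1, 1], 9)


def test_permanova_seeded_runs_reproducible(toy_distance_six):
    dist, codes = toy_distance_six
    a = permanova(dist, codes, n_permutations=199, seed=9)
    b = permanova(dist, codes, n_permutations=199, seed=9)
    assert (a.p, a.pseudo_F) == (b.p, b.pseudo_F)


def test_pairwise_pseudo_t_is_sqrt_of_pair_F():
    rng = np.random.default_rng(13)
    X = rng.random((12, 5))
    codes = np.repeat([0, 1, 2], 4)
    dist = bray_curtis(abundance_frame(X))
    pairs = permanova_pairwise(dist, codes, n_permutations=99, seed=1)
    assert len(pairs) == 3
    for pr in pairs:
        idx = np.flatnonzero(np.isin(codes, [int(pr.group_a), int(pr.group_b)]))
        f_pair = brute_permanova_F(dist.D[np.ix_(idx, idx)], codes[idx])
        assert pr.pseudo_t**2 == pytest.approx(f_pair, abs=1e-12)


def test_pairwise_null_case_large_p():
    rng = np.random.default_rng(3)
    base = rng.random((4, 5))
    X = np.vstack([base + rng.normal(scale=1e-3, size=base.shape) for _ in range(2)])
    codes = np.repeat([0, 1], 4)
    dist = bray_curtis(abundance_frame(X))
    pairs = permanova_pairwise(dist, codes, n_permutations=199, seed=2)
    assert pairs[0].p > 0.3


def test_pairwise_holm_adjustment_monotone():
    rng = np.random.default_rng(17)
    X = rng.random((12, 5))
    codes = np.repeat([0, 1, 2], 4)
    dist = bray_curtis(abundance_frame(X))
    raw = permanova_pairwise(dist, codes, 99, seed=1)
    adj = permanova_pairwise(dist, codes, 99, seed=1, adjust="holm")
    for r, a in zip(raw, adj):
        assert a.p >= r.p - 1e-12


def test_block_permutation_respects_blocks():
    """With one sample per block per group, block shuffling only swaps within blocks."""
    rng = np.random.default_rng(4)
    X = rng.random((8, 5))
    codes = np.repeat([0, 1], 4)
    blocks = list(range(4)) * 2
    dist = bray_curtis(abundance_frame(X))
    res = permanova(dist, codes, n_permutations=199, seed=5, blocks=blocks)
    assert 0 < res.p <= 1.0


# -- Pearson ------------------------------------------------------------------


def test_pearson_known_values():
    res = pearson([1, 2, 3, 4], [3, 5, 7, 9])  # y = 2x + 1
    assert (res.r, res.r2) == (1.0, 1.0)
    res = pearson([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.r == pytest.approx(0.6, abs=1e-12)
    assert res.r2 == pytest.approx(0.36, abs=1e-12)
    # orthogonal construction: zero correlation
    res = pearson([1, 2, 3], [1, 0, 1])
    assert res.r == pytest.approx(0.0, abs=1e-12)


def test_pearson_p_matches_scipy():
    import scipy.stats

    rng = np.random.default_rng(2)
    x, y = rng.random(20), rng.random(20)
    ours = pearson(x, y)
    r_ref, p_ref = scipy.stats.pearsonr(x, y)
    assert ours.r == pytest.approx(r_ref, abs=1e-12)
    assert ours.p == pytest.approx(p_ref, abs=1e-10)


def test_pearson_degenerate_inputs_rejected():
    with pytest.raises(ContractError):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(ContractError):
        pearson([1, 2], [1, 2])
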