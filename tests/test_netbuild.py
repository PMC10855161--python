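"""Co-expression adjacency, binarization, power selection, subject graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trustomics import netbuild, simdata
from trustomics.simdata import OmicsMatrix, SimSpec


def make_matrix(values):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(values=values,
                       subject_ids=[f"s{i}" for i in range(values.shape[0])],
                       feature_names=[f"f{j}" for j in range(values.shape[1])])


def brute_force_adjacency(values: np.ndarray, beta: float) -> np.ndarray:
    """Independent oracle: textbook Pearson, pair by pair, then power."""
    n, d = values.shape
    a = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            vi, vj = values[:, i], values[:, j]
            num = np.sum((vi - vi.mean()) * (vj - vj.mean()))
            den = np.sqrt(np.sum((vi - vi.mean()) ** 2)
                          * np.sum((vj - vj.mean()) ** 2))
            r = num / den
            a[i, j] = a[j, i] = ((1 + r) / 2) ** beta
    return a


class TestComputeAdjacency:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for beta in (1.0, 2.0, 6.0):
            values = rng.standard_normal((10, 8))
            a = netbuild.compute_adjacency(make_matrix(values), beta)
            np.testing.assert_allclose(
                a, brute_force_adjacency(values, beta), atol=1e-10)

    def test_affine_copy_gives_unit_adjacency(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        values = np.column_stack([base, 3.0 * base + 2.0, -base])
        a = netbuild.compute_adjacency(make_matrix(values), beta=4.0)
        assert a[0, 1] == pytest.approx(1.0)      # r = +1
        assert a[0, 2] == pytest.approx(0.0)      # r = -1

    def test_uncorrelated_pair_gives_half_to_the_beta(self):
        values = np.array([[1.0, 1.0], [2.0, 1.0], [1.0, 2.0], [2.0, 2.0]])
        a = netbuild.compute_adjacency(make_matrix(values), beta=2.0)
        assert a[0, 1] == pytest.approx(0.25)     # r = 0 -> 0.5 ** 2

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((15, 5))
        scaled = values * rng.uniform(0.5, 3.0, size=5) + rng.normal(size=5)
        a1 = netbuild.compute_adjacency(make_matrix(values), 3.0)
        a2 = netbuild.compute_adjacency(make_matrix(scaled), 3.0)
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_zero_variance_feature_rejected_with_pointer(self):
        values = np.random.default_rng(0).standard_normal((10, 3))
        values[:, 1] = 2.0
        with pytest.raises(ValueError, match="filter_low_signal"):
            netbuild.compute_adjacency(make_matrix(values), 2.0)


class TestBinarize:
    def test_paper_default_threshold_keeps_midrange_edge(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        e = netbuild.binarize(a, 0.08)
        assert e[0, 1] == 1 and e[0, 0] == 0

    def test_threshold_above_max_yields_empty_graph(self):
        rng = np.random.default_rng(3)
        a = netbuild.compute_adjacency(
            make_matrix(rng.standard_normal((20, 6))), 6.0)
        hi = np.triu(a, 1).max() + 1e-6
        assert netbuild.binarize(a, min(hi, 0.999)).sum() == 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        a = netbuild.compute_adjacency(
            make_matrix(rng.standard_normal((12, 6))), 3.0)
        e_low = netbuild.binarize(a, 0.1)
        e_high = netbuild.binarize(a, 0.4)
        assert np.array_equal(e_low, e_low.T)
        assert np.all(e_high <= e_low)            # raising threshold never adds
        assert np.diag(e_low).sum() == 0


class TestSelectBeta:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(4)
        x = make_matrix(rng.standard_normal((30, 10)))
        assert netbuild.select_beta(x, candidates=[7], fit_target=0.99) == 7.0

    def test_vacuous_target_returns_smallest(self):
        rng = np.random.default_rng(5)
        x = make_matrix(rng.standard_normal((30, 10)))
        assert netbuild.select_beta(x, fit_target=0.0) == 1.0

    def test_reproducible_on_module_structured_data(self):
        spec = SimSpec(seed=6, n_subjects=100, n_features=(30,),
                       module_sizes=((10, 10, 10),), within_module_rho=0.7,
                       informative_fraction=(0.0,))
        (x,), _ = simdata.generate_cohort(spec)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = netbuild.select_beta(x, fit_target=0.5)
            b2 = netbuild.select_beta(x, fit_target=0.5)
        assert b1 == b2


class TestThresholdGridSearch:
    def test_single_point_grid(self):
        a = np.eye(3)
        assert netbuild.threshold_grid_search(a, grid=[0.3]) == 0.3

    def test_density_criterion_picks_banded_candidate(self):
        rng = np.random.default_rng(7)
        a = netbuild.compute_adjacency(
            make_matrix(rng.standard_normal((40, 12))), 4.0)
        grid = [0.05, 0.2, 0.35, 0.5]
        densities = {t: netbuild.binarize(a, t).sum() / (12 * 11)
                     for t in grid}
        in_band = [t for t in grid if 0.05 <= densities[t] <= 0.30]
        chosen = netbuild.threshold_grid_search(
            a, grid=grid, criterion=netbuild.density_band_criterion(0.05, 0.3))
        if in_band:
            assert chosen == min(in_band)        # ties -> smallest threshold

    def test_default_grid_spans_005_to_05(self):
        assert netbuild.DEFAULT_GRID[0] == 0.05
        assert netbuild.DEFAULT_GRID[-1] == 0.5


class TestSubjectGraphs:
    def test_one_graph_per_subject_sharing_edges(self):
        spec = SimSpec(seed=8, n_subjects=12, n_features=(8,),
                       module_sizes=((4, 4),), informative_fraction=(0.0,))
        (x,), _ = simdata.generate_cohort(spec)
        net = netbuild.build_network(x, beta=2.0, threshold=0.08)
        graphs = netbuild.build_subject_graphs(x, net.edge_matrix)
        assert len(graphs) == 12
        assert all(g.edge_matrix is net.edge_matrix for g in graphs)
        np.testing.assert_allclose(graphs[3].node_features, x.values[3])

    def test_zero_subject_keeps_structure(self):
        x = make_matrix(np.vstack([np.zeros(4),
                                   np.random.default_rng(0).standard_normal(
                                       (5, 4))]))
        e = np.ones((4, 4), dtype=np.int8) - np.eye(4, dtype=np.int8)
        graphs = netbuild.build_subject_graphs(x, e)
        assert (graphs[0].node_features == 0).all()
        assert np.array_equal(graphs[0].edge_matrix, e)

    def test_dimension_mismatch_rejected(self):
        x = make_matrix(np.ones((3, 4)) + np.arange(12).reshape(3, 4))
        with pytest.raises(ValueError):
            netbuild.build_subject_graphs(x, np.zeros((5, 5)))


def test_network_round_trips_through_edge_list(tmp_path):
    rng = np.random.default_rng(11)
    x = make_matrix(rng.standard_normal((25, 9)))
    net = netbuild.build_network(x, beta=3.0, threshold=0.2)
    netbuild.save_network(net, tmp_path / "net")
    back = netbuild.load_network(tmp_path / "net")
    assert np.array_equal(back.edge_matrix, net.edge_matrix)
    assert back.beta == net.beta and back.threshold == net.threshold
    assert back.feature_names == net.feature_names
    mask = net.edge_matrix == 1
    np.testing.assert_allclose(back.adjacency[mask], net.adjacency[mask],
                               rtol=1e-15)
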