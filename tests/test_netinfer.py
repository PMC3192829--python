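import numpy as np
import pytest
from scipy import stats

import glyconet as g
from glyconet.netinfer import (
    TooFewEigenvaluesError,
    default_tau_grid,
    group_correlation_boundary,
    unfold_eigenvalues,
)
from glyconet.synthetic import SyntheticSpec

from conftest import make_design, make_matrix


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    assert n % 3 == 0
    conds = [("glucose", "mid"), ("xylose", "mid"), ("fructose", "mid"),
             ("cellobiose", "mid")][: n // 3]
    return make_matrix(values, make_design(conds))


def goe(n, seed):
    a = np.random.default_rng(seed).standard_normal((n, n))
    return (a + a.T) / np.sqrt(2)


class TestPearson:
    @pytest.mark.parametrize(
        "y,expected", [((2, 4, 6), 1.0), ((3, 2, 1), -1.0), ((1, 3, 2), 0.5)]
    )
    def test_hand_examples(self, y, expected):
        x = matrix_from([[1, 2, 3], list(y)])
        c = g.pearson_matrix(x, min_pairs=3)
        assert c.r[0, 1] == pytest.approx(expected, abs=1e-12)
        assert c.r[1, 0] == c.r[0, 1]

    def test_matches_numpy_corrcoef_unmasked(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(15, 12))
        c = g.pearson_matrix(matrix_from(vals), min_pairs=3)
        np.testing.assert_allclose(c.r, np.corrcoef(vals), atol=1e-12)

    def test_pairwise_complete_matches_per_pair_pearsonr(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 12))
        snr = np.where(rng.random((8, 12)) < 0.25, 1.0, 30.0)
        x = matrix_from(vals)
        x.snr = snr
        x.mask = snr >= 2.0
        c = g.pearson_matrix(x, min_pairs=3)
        for i in range(8):
            for j in range(i + 1, 8):
                joint = x.mask[i] & x.mask[j]
                if joint.sum() < 3:
                    assert not c.usable[i, j]
                    continue
                expected = stats.pearsonr(vals[i, joint], vals[j, joint]).statistic
                assert c.r[i, j] == pytest.approx(expected, abs=1e-10)
                assert c.n_pairs[i, j] == joint.sum()

    def test_zero_variance_gene_flagged_unusable(self):
        vals = np.vstack([np.full(6, 2.0), np.random.default_rng(2).normal(size=(2, 6))])
        c = g.pearson_matrix(matrix_from(vals), min_pairs=3)
        assert not c.usable[0, 1] and not c.usable[0, 2]
        assert np.isfinite(c.r).all()

    def test_min_pairs_flags_sparse_pairs(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(2, 12))
        x = matrix_from(vals)
        m = np.ones((2, 12), dtype=bool)
        m[0, :8] = False
        x.mask = m
        c = g.pearson_matrix(x, min_pairs=9)
        assert not c.usable[0, 1]
        c2 = g.pearson_matrix(x, min_pairs=4)
        assert c2.usable[0, 1]


class TestNnsd:
    def test_unfolded_spacing_mean_is_one(self):
        eigs = np.linalg.eigvalsh(goe(600, 5))
        unfolded = unfold_eigenvalues(eigs)
        spacings = np.diff(unfolded)
        assert abs(spacings.mean() - 1.0) < 0.05

    def test_exponential_spacings_accept_poisson_reject_goe(self):
        rng = np.random.default_rng(42)
        eigs = np.cumsum(rng.exponential(1.0, size=2000))
        res = g.nnsd_statistics(eigs)
        assert res.p_poisson > 0.05
        assert res.p_goe < 1e-6
        assert res.chi2_goe > res.chi2_poisson

    def test_goe_matrix_accepts_wigner_rejects_poisson(self):
        res = g.nnsd_statistics(np.linalg.eigvalsh(goe(500, 0)))
        assert res.p_poisson < 1e-3
        assert res.p_goe > 1e-3

    def test_block_diagonal_superposition_accepts_poisson(self):
        eigs = np.concatenate(
            [np.linalg.eigvalsh(goe(100, 1000 + b)) for b in range(10)]
        )
        res = g.nnsd_statistics(eigs)
        assert res.p_poisson > 1e-3

    def test_too_few_eigenvalues_error(self):
        with pytest.raises(TooFewEigenvaluesError, match="lower"):
            g.nnsd_statistics(np.arange(50.0))

    def test_degenerate_eigenvalues_collapse(self):
        eigs = np.concatenate([np.zeros(500), np.linspace(1, 2, 120)])
        res = g.nnsd_statistics(eigs)
        assert res.n_eigenvalues == 121


class TestThresholdScan:
    def test_edge_count_monotone_in_tau(self):
        rng = np.random.default_rng(7)
        x = matrix_from(rng.normal(size=(60, 12)))
        c = g.pearson_matrix(x, min_pairs=3)
        grid = np.round(np.arange(0.3, 0.95, 0.05), 2)
        scan = g.rmt_threshold_scan(c, tau_grid=grid, min_eigs=10)
        assert (np.diff(scan.n_edges) <= 0).all()

    def test_edge_sets_nest_in_tau(self):
        rng = np.random.default_rng(8)
        x = matrix_from(rng.normal(size=(40, 12)))
        c = g.pearson_matrix(x, min_pairs=3)
        prev = None
        for tau in (0.3, 0.5, 0.7, 0.9):
            edges = {frozenset(e) for e in
                     g.build_network(c, tau, mode="abs").graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_pure_noise_scan_warns_or_is_sparse(self):
        spec = SyntheticSpec(n_genes=300, modules=(), n_negative_controls=0,
                             snr_dropout_rate=0.0, seed=13)
        x, _ = g.simulate(spec)
        c = g.pearson_matrix(x)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = g.rmt_threshold_scan(c)
        n_pairs = 300 * 299 / 2
        assert scan.warning or scan.n_edges[scan.selected_index] <= 0.01 * n_pairs

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(9)
        c = g.pearson_matrix(matrix_from(rng.normal(size=(10, 6))), min_pairs=3)
        with pytest.raises(ValueError):
            g.rmt_threshold_scan(c, tau_grid=np.array([]))

    def test_selected_tau_in_grid(self, preset_result):
        scan = preset_result.scan
        assert scan.selected_tau in scan.candidates
        assert not scan.warning


class TestBuildNetwork:
    def three_gene_corr(self, r01, r02, r12):
        c = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        return g.CorrelationMatrix(
            genes=["a", "b", "c"], r=c, n_pairs=np.full((3, 3), 33),
            usable=np.ones((3, 3), bool), min_pairs=9,
        )

    def test_direct_thresholding(self):
        net = g.build_network(self.three_gene_corr(0.95, 0.96, 0.93), 0.94)
        assert net.n_edges == 2 and net.n_nodes == 3

    def test_all_below_cutoff_gives_empty_network(self):
        net = g.build_network(self.three_gene_corr(0.5, 0.2, -0.9), 0.94, mode="abs")
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_positive_mode_drops_negative_edges(self):
        net_abs = g.build_network(self.three_gene_corr(0.95, -0.97, 0.1), 0.94, mode="abs")
        net_pos = g.build_network(self.three_gene_corr(0.95, -0.97, 0.1), 0.94, mode="positive")
        assert net_abs.n_edges == 2 and net_pos.n_edges == 1
        signs = {d["sign"] for _, _, d in net_abs.graph.edges(data=True)}
        assert signs == {"+", "-"}

    def test_network_nodes_track_planted_members(self, preset_result):
        truth = preset_result.truth
        planted = len(truth.planted_genes())
        assert abs(preset_result.network.n_nodes - planted) <= 0.15 * planted

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            g.build_network(self.three_gene_corr(0.9, 0.9, 0.9), 1.5)


def test_group_boundary_on_separated_blocks():
    r = np.eye(6)
    r[:3, :3] = 0.95
    r[3:, 3:] = 0.9
    r[0, 3] = r[3, 0] = 0.42
    np.fill_diagonal(r, 1.0)
    c = g.CorrelationMatrix(genes=[f"g{i}" for i in range(6)], r=r,
                            n_pairs=np.full((6, 6), 33),
                            usable=np.ones((6, 6), bool), min_pairs=9)
    groups = {"g0": "A", "g1": "A", "g2": "A", "g3": "B", "g4": "B", "g5": "B"}
    boundary, max_between = group_correlation_boundary(
        c, groups, tau_grid=default_tau_grid()
    )
    assert max_between == pytest.approx(0.42)
    assert boundary == 0.70
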