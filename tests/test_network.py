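import numpy as np
import pytest

from coexdiff.containers import ValidationError
from coexdiff.network import (
    TreeCutParams,
    bicor_matrix,
    consensus_modules,
    cut_modules,
    default_tree_cut_grid,
    pick_soft_threshold,
    scale_free_fit,
    signed_tom,
    soft_adjacency,
)
from oracles import bicor_matrix_oracle, tom_oracle


class TestBicor:
    def test_self_and_antiself(self, rng):
        x = rng.normal(size=(2, 20))
        x[1] = -x[0]
        c = bicor_matrix(x)
        assert np.isclose(c[0, 0], 1.0)
        assert np.isclose(c[0, 1], -1.0)

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=(3, 25))
        y = x.copy()
        y[1] = 2.5 * y[1] + 7.0
        assert np.allclose(bicor_matrix(x), bicor_matrix(y), atol=1e-12)

    def test_matches_formula_oracle(self, rng):
        x = rng.normal(size=(30, 15))
        assert np.allclose(
            bicor_matrix(x), bicor_matrix_oracle(x), atol=1e-10
        )

    def test_zero_mad_rows_fall_back_to_pearson(self, rng):
        x = rng.normal(size=(3, 12))
        x[0, :] = np.where(np.arange(12) == 0, 5.0, 1.0)  # MAD 0
        c = bicor_matrix(x)
        assert np.all(np.isfinite(c))
        assert np.allclose(np.diag(c), 1.0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            bicor_matrix(rng.normal(size=(5, 3)))


class TestSoftThreshold:
    def test_power_law_degrees_reach_threshold(self, rng):
        # connectivity drawn from a discrete power law has a straight
        # log-log frequency plot, the topology the criterion targets
        k = np.round(
            (rng.pareto(1.5, size=4000) + 1.0) * 3
        )
        fit, slope = scale_free_fit(k)
        assert fit > 0.8
        assert slope < 0

    def test_quoted_default_threshold(self):
        import inspect

        sig = inspect.signature(pick_soft_threshold)
        assert sig.parameters["r2_threshold"].default == 0.8

    def test_degenerate_correlation_warns_not_crashes(self, rng):
        corr = np.eye(40) + rng.normal(scale=1e-4, size=(40, 40))
        corr = np.clip((corr + corr.T) / 2, -1, 1)
        np.fill_diagonal(corr, 1.0)
        with pytest.warns(UserWarning):
            beta, table, warned = pick_soft_threshold(corr, (1, 2, 3))
        assert warned
        assert beta in (1, 2, 3)

    def test_smallest_passing_power_selected(self, small_study):
        ds = small_study.datasets[0]
        corr = bicor_matrix(ds.values.to_numpy())
        beta, table, warned = pick_soft_threshold(corr)
        eligible = table[table["mean_k"] >= 1.0]
        passing = eligible[eligible["sft_r2"] > 0.8]
        if not warned:
            assert beta == passing["power"].iloc[0]
        else:
            assert passing.empty


class TestSignedTOM:
    def test_three_gene_hand_example(self):
        a = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        t = signed_tom(a)
        assert np.isclose(t[1, 2], (0.25 + 0) / (0.5 + 1 - 0))

    def test_complete_graph_has_maximal_overlap(self):
        a = np.ones((6, 6))
        t = signed_tom(a)
        off = t[~np.eye(6, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.uniform(size=(30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(signed_tom(a), tom_oracle(a), atol=1e-12)

    def test_asymmetric_input_rejected(self, rng):
        a = rng.uniform(size=(5, 5))
        with pytest.raises(ValidationError):
            signed_tom(a)

    def test_shared_neighbor_monotonicity(self, rng):
        # strengthening a shared neighbour never decreases TOM(i,j)
        a = rng.uniform(0.1, 0.5, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        before = signed_tom(a)[0, 1]
        a2 = a.copy()
        a2[0, 2] = a2[2, 0] = 0.9
        a2[1, 2] = a2[2, 1] = 0.9
        after = signed_tom(a2)[0, 1]
        assert after >= before

    def test_dissimilarity_bounds(self, rng):
        a = rng.uniform(size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        d = 1.0 - signed_tom(a)
        assert d.min() >= -1e-12 and d.max() <= 1 + 1e-12
        assert np.allclose(np.diag(d), 0.0)


def _planted_dissimilarity(rng, sizes=(20, 20), intra=0.2, inter=0.95):
    n = sum(sizes)
    d = np.full((n, n), inter)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = intra
        start += s
    d += rng.normal(scale=0.01, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


class TestCutModules:
    def test_two_planted_blocks_recovered(self, rng):
        d = _planted_dissimilarity(rng)
        genes = [f"G{i}" for i in range(40)]
        part = cut_modules(
            d, genes, TreeCutParams(min_module_size=10, deep_split=2,
                                    max_dissimilarity=0.2)
        )
        assert len(part.module_labels()) == 2
        sizes = sorted(part.sizes().values())
        assert sizes == [20, 20]
        # members coincide with the planted blocks
        first = set(part.members(part.labels["G0"]))
        assert first == {f"G{i}" for i in range(20)}

    def test_unassigned_genes_possible_with_pam_off(self, rng):
        # background genes beyond the planted blocks stay grey
        d = _planted_dissimilarity(rng, sizes=(15, 15))
        n_extra = 20
        n = d.shape[0] + n_extra
        full = rng.uniform(0.93, 1.0, size=(n, n))
        full = (full + full.T) / 2
        full[:30, :30] = d
        np.fill_diagonal(full, 0.0)
        genes = [f"G{i}" for i in range(n)]
        part = cut_modules(
            full, genes, TreeCutParams(min_module_size=10, deep_split=2,
                                       max_dissimilarity=0.2)
        )
        assert part.n_unassigned() > 0

    def test_uniform_random_dissimilarity_yields_no_large_module(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            local = np.random.default_rng(seed)
            d = local.uniform(size=(80, 80))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            part = cut_modules(
                d, [f"G{i}" for i in range(80)],
                TreeCutParams(min_module_size=10, deep_split=2,
                              max_dissimilarity=0.1),
            )
            sizes = list(part.sizes().values())
            if sizes and max(sizes) > 40:  # a chance module spanning half
                hits += 1
        assert hits <= 0.1 * n_seeds

    def test_fewer_genes_than_min_size_all_grey(self, rng):
        d = _planted_dissimilarity(rng, sizes=(3, 3))
        with pytest.warns(UserWarning):
            part = cut_modules(
                d, [f"G{i}" for i in range(6)],
                TreeCutParams(min_module_size=10),
            )
        assert part.n_unassigned() == 6


class TestConsensus:
    def test_default_grid_enumerates_sixty_cases(self):
        grid = default_tree_cut_grid()
        assert len(grid) == 60
        assert {p.min_module_size for p in grid} == {50, 60, 70, 80, 90, 100}
        assert {p.deep_split for p in grid} == {0, 1, 2, 3, 4}
        assert {p.max_dissimilarity for p in grid} == {0.1, 0.2}
        assert not any(p.pam_stage for p in grid)

    def test_identical_grid_cases_have_full_stability(self, rng):
        d = _planted_dissimilarity(rng)
        genes = [f"G{i}" for i in range(40)]
        grid = [TreeCutParams(10, 2, 0.2)] * 4
        part, table = consensus_modules(d, genes, grid)
        assert (table["stability"] == 1.0).all()

    def test_planted_three_blocks_recovered_with_high_ari(self, rng):
        from sklearn.metrics import adjusted_rand_score

        d = _planted_dissimilarity(rng, sizes=(25, 20, 15))
        genes = [f"G{i}" for i in range(60)]
        grid = [
            TreeCutParams(ms, ds_, 0.2)
            for ms in (10, 12) for ds_ in (1, 2, 3)
        ]
        part, _ = consensus_modules(d, genes, grid)
        truth = [0] * 25 + [1] * 20 + [2] * 15
        ari = adjusted_rand_score(truth, part.labels.to_numpy())
        assert ari >= 0.8
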