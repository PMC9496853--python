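import numpy as np
import pandas as pd
import pytest

from coexdiff.containers import ExpressionDataset, ValidationError
from coexdiff.modules import (
    GOC,
    LOC,
    ModuleReport,
    dcoe_criterion,
    de_criterion,
    evaluate_modules,
    intramodular_connectivity,
    module_eigengene,
    select_modules,
)
from coexdiff.simulate import SimulationConfig, generate_study
from oracles import connectivity_oracle, ols_two_group_oracle
from scipy import stats


def _dataset(values, n_dis, n_con):
    cols = [f"s{i}" for i in range(n_dis + n_con)]
    cond = pd.Series(["disease"] * n_dis + ["control"] * n_con, index=cols)
    return ExpressionDataset(
        pd.DataFrame(values, columns=cols,
                     index=[f"G{i}" for i in range(values.shape[0])]),
        cond,
        pd.Series("ds", index=cols),
    )


class TestModuleEigengene:
    def test_identical_genes_give_standardized_profile(self, rng):
        profile = rng.normal(size=16)
        values = np.tile(profile, (4, 1))
        ds = _dataset(values, 8, 8)
        me, var = module_eigengene(ds, ds.gene_ids)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(me.to_numpy()), np.abs(z), atol=1e-8)
        assert var == pytest.approx(1.0)

    def test_sign_aligned_with_mean_profile(self, rng):
        x = rng.normal(size=(10, 20)) + rng.normal(size=20)
        ds = _dataset(x, 10, 10)
        me, _ = module_eigengene(ds, ds.gene_ids)
        z = x - x.mean(axis=1, keepdims=True)
        z /= z.std(axis=1, ddof=1, keepdims=True)
        assert me.to_numpy() @ z.mean(axis=0) >= 0
        # flipping every gene flips the (aligned) eigengene
        ds_flip = _dataset(-x, 10, 10)
        me_flip, _ = module_eigengene(ds_flip, ds_flip.gene_ids)
        assert np.allclose(me.to_numpy(), -me_flip.to_numpy(), atol=1e-8)

    def test_variance_explained_matches_eigen_oracle(self, rng):
        x = rng.normal(size=(12, 30))
        ds = _dataset(x, 15, 15)
        _, var = module_eigengene(ds, ds.gene_ids)
        z = x - x.mean(axis=1, keepdims=True)
        z /= z.std(axis=1, ddof=1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)
        assert var == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_too_few_genes_rejected(self, rng):
        ds = _dataset(rng.normal(size=(3, 10)), 5, 5)
        with pytest.raises(ValidationError):
            module_eigengene(ds, ["G0"])


class TestDECriterion:
    def test_constant_across_conditions_gives_zero_beta(self):
        me = pd.Series([0.5] * 10, index=[f"s{i}" for i in range(10)])
        status = pd.Series(["disease"] * 5 + ["control"] * 5, index=me.index)
        with pytest.warns(UserWarning):
            beta, p = de_criterion(me, status)
        assert beta == 0.0 and p == 1.0

    def test_perfect_association(self):
        idx = [f"s{i}" for i in range(10)]
        status = pd.Series(["disease"] * 5 + ["control"] * 5, index=idx)
        me = pd.Series([1.0] * 5 + [0.0] * 5, index=idx)
        beta, p = de_criterion(me, status)
        assert beta == pytest.approx(1.0)
        assert p < 1e-8

    def test_matches_two_sample_oracle(self, rng):
        idx = [f"s{i}" for i in range(30)]
        status = pd.Series(["disease"] * 14 + ["control"] * 16, index=idx)
        me = pd.Series(rng.normal(size=30), index=idx)
        beta, p = de_criterion(me, status)
        ind = (status == "disease").to_numpy().astype(int)
        beta_o, p_o = ols_two_group_oracle(me.to_numpy(), ind)
        assert beta == pytest.approx(beta_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)


class TestIntramodularConnectivity:
    def test_two_gene_module(self):
        a = np.array([[1.0, 0.7], [0.7, 1.0]])
        k = intramodular_connectivity(a, ["A", "B"], ["A", "B"])
        assert np.allclose(k.to_numpy(), [0.7, 0.7])

    def test_zero_adjacency_gives_zeros(self):
        a = np.zeros((4, 4))
        k = intramodular_connectivity(a, list("ABCD"), list("ABC"))
        assert (k == 0).all()

    def test_matches_row_sum_oracle(self, rng):
        n = 60
        a = rng.uniform(size=(n, n))
        a = (a + a.T) / 2
        genes = [f"G{i}" for i in range(n)]
        module = [genes[i] for i in rng.choice(n, size=50, replace=False)]
        k = intramodular_connectivity(a, genes, module)
        idx = [genes.index(g) for g in module]
        assert np.allclose(k.to_numpy(), connectivity_oracle(a, idx),
                           atol=1e-10)


class TestDcoECriterion:
    def test_identical_vectors_null(self):
        k = pd.Series([1.0, 2.0, 3.0, 4.0])
        t, p, bonf, _ = dcoe_criterion(k, k, 5)
        assert t == 0.0 and p == 1.0 and bonf == 1.0

    def test_argument_swap_negates_t(self, rng):
        kd = pd.Series(rng.uniform(size=20))
        kc = pd.Series(rng.uniform(size=20))
        t1, p1, _, d1 = dcoe_criterion(kd, kc, 3)
        t2, p2, _, d2 = dcoe_criterion(kc, kd, 3)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert {d1, d2} == {GOC, LOC}

    def test_matches_one_sample_t_oracle(self, rng):
        kd = pd.Series(rng.uniform(size=25))
        kc = pd.Series(rng.uniform(size=25))
        t, p, bonf, _ = dcoe_criterion(kd, kc, 7)
        t_o, p_o = stats.ttest_1samp(kd.to_numpy() - kc.to_numpy(), 0.0)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        assert bonf == pytest.approx(min(1.0, p_o * 7))


def _report(label, de_p, dcoe, direction=GOC, beta=0.1):
    rep = ModuleReport(label=label, size=50)
    rep.de = {"ds1": (beta, de_p[0]), "ds2": (beta, de_p[1])}
    rep.dcoe = {
        "ds1": (2.0, 0.01, dcoe[0], direction),
        "ds2": (2.0, 0.01, dcoe[1], direction),
    }
    rep.expression_direction = "up" if beta > 0 else "down"
    return rep


class TestSelectModules:
    def test_de_only_module_not_selected(self):
        rep = _report("m", de_p=(0.001, 0.2), dcoe=(0.5, 0.9))
        assert select_modules([rep]) == []

    def test_dual_criterion_selects(self):
        rep = _report("m", de_p=(0.001, 0.2), dcoe=(0.01, 0.02))
        out = select_modules([rep])
        assert out == [rep]
        assert rep.concordant is True  # up + GOC

    def test_inconsistent_direction_blocks_selection(self):
        rep = _report("m", de_p=(0.001, 0.2), dcoe=(0.01, 0.02))
        t, p, bonf, _ = rep.dcoe["ds2"]
        rep.dcoe["ds2"] = (t, p, bonf, LOC)
        assert select_modules([rep]) == []

    def test_selection_invariant_to_label_and_order(self):
        reps = [
            _report("a", de_p=(0.001, 0.2), dcoe=(0.01, 0.02)),
            _report("b", de_p=(0.5, 0.5), dcoe=(0.01, 0.02)),
        ]
        sel1 = {r.label for r in select_modules(list(reps))}
        renamed = [
            _report("zzz", de_p=(0.001, 0.2), dcoe=(0.01, 0.02)),
            _report("b", de_p=(0.5, 0.5), dcoe=(0.01, 0.02)),
        ]
        sel2 = {r.label for r in select_modules(renamed[::-1])}
        assert sel1 == {"a"} and sel2 == {"zzz"}


class TestPlantedSignalRecovery:
    """Module-level power and type-I on the generator's planted signal."""

    @staticmethod
    def _run(reps, seed0):
        power_hits, null_hits = 0, 0
        for r in range(reps):
            config = SimulationConfig(
                n_genes=120,
                module_sizes=(50, 50),
                samples_per_condition={"ds1": (50, 50), "ds2": (50, 50)},
                base_corr=0.3,
                dcoe_corr=0.7,
                dcoe_module_ids=(0,),
                de_shift=0.5,
                de_module_ids=(0,),
                seed=seed0 + r,
            )
            study = generate_study(config)
            by_id = {d.batch.iloc[0]: d for d in study.datasets}
            reports = evaluate_modules(by_id, study.truth_modules, beta=6)
            selected = {m.label for m in select_modules(reports)}
            signal = study.truth_dcoe[0]
            null = next(
                m for m in study.truth_modules.module_labels() if m != signal
            )
            power_hits += signal in selected
            null_hits += null in selected
        return power_hits / reps, null_hits / reps

    def test_planted_module_power_and_null_control(self):
        power, type1 = self._run(reps=30, seed0=5000)
        assert power >= 0.95
        assert type1 <= 0.10  # loose at 30 reps; acceptance uses 100
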