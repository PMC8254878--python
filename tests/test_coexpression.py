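"""Co-expression network core: adjacency, soft threshold, TOM, modules,
eigengenes, module-trait statistics, kME."""

import numpy as np
import pandas as pd
import pytest

from amelonet import PipelineConfig, SimulationPlan, simulate_expression
from amelonet.coexpression import (
    GREY,
    ExpressionDataset,
    ExpressionError,
    adjacency,
    build_network,
    correlation_p_value,
    detect_modules,
    kme_table,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    topological_overlap,
)

from _oracles import random_adjacency, tom_triple_loop


def dataset(x, trait=None):
    x = np.asarray(x, dtype=float)
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = [f"s{j}" for j in range(x.shape[1])]
    trait = np.zeros(x.shape[1], dtype=int) if trait is None else trait
    return ExpressionDataset(
        matrix=pd.DataFrame(x, index=genes, columns=samples), trait=trait
    )


class TestAdjacency:
    def test_identical_profiles_give_one(self):
        x = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 2)
        a = adjacency(dataset(x), power=12)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 0] == 0.0  # diagonal zeroed

    def test_power_twelve_arithmetic(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        noise = rng.normal(size=200)
        x = np.vstack([base, base + noise * 0.5])
        r = abs(np.corrcoef(x)[0, 1])
        a = adjacency(dataset(x), power=12)
        assert a[0, 1] == pytest.approx(r**12, rel=1e-12)

    def test_power_one_is_abs_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 10))
        a = adjacency(dataset(x), power=1)
        expected = np.abs(np.corrcoef(x))
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(a, expected)

    def test_zero_variance_gene_rejected(self):
        x = np.vstack([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ExpressionError):
            adjacency(dataset(x), power=6)


class TestSoftThreshold:
    def test_selection_rule_on_modular_data(self):
        # the planted block world is bimodal in connectivity, not scale
        # free, so no power reaches the 0.85 target at 12 samples and the
        # chosen power must be the signed-fit argmax
        expr, _ = simulate_expression(SimulationPlan(seed=11))
        power, table = pick_soft_threshold(expr)
        assert set(table.columns) == {"power", "fit_r2", "mean_k"}
        ok = table.dropna(subset=["fit_r2"])
        if (ok["fit_r2"] >= 0.85).any():
            reaching = ok[ok["fit_r2"] >= 0.85]
            assert power == int(reaching["power"].iloc[0])
        else:
            assert power == int(ok.loc[ok["fit_r2"].idxmax(), "power"])

    def test_smallest_power_reaching_target_is_chosen(self):
        # two huge loose blocks yield a decaying k histogram whose log-log
        # fit is nearly perfect, so the 0.85 rule engages at low power
        rng = np.random.default_rng(15)
        f = rng.normal(size=(2, 40))
        x = np.empty((200, 40))
        for i in range(200):
            x[i] = 0.55 * f[i % 2] + rng.normal(scale=1.0, size=40)
        expr = dataset(x)
        power, table = pick_soft_threshold(expr)
        ok = table.dropna(subset=["fit_r2"])
        reaching = ok[ok["fit_r2"] >= 0.85]
        if len(reaching):
            assert power == int(reaching["power"].iloc[0])
        else:
            assert power == int(ok.loc[ok["fit_r2"].idxmax(), "power"])

    def test_pure_noise_falls_back_to_argmax(self):
        rng = np.random.default_rng(4)
        expr = dataset(rng.normal(size=(120, 12)))
        power, table = pick_soft_threshold(expr)
        ok = table.dropna(subset=["fit_r2"])
        assert (ok["fit_r2"] < 0.85).all()
        assert power == int(ok.loc[ok["fit_r2"].idxmax(), "power"])

    def test_mean_connectivity_decreases_with_power(self):
        expr, _ = simulate_expression(SimulationPlan(seed=2))
        _, table = pick_soft_threshold(expr)
        mean_k = table["mean_k"].to_numpy()
        assert np.all(np.diff(mean_k) <= 1e-12)


class TestTOM:
    def test_clique_of_ones_is_one(self):
        a = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(topological_overlap(a), 1.0)

    def test_zero_adjacency_gives_zero_off_diagonal(self):
        tom = topological_overlap(np.zeros((4, 4)))
        off = tom[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)
        assert np.all(np.diag(tom) == 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(9)
        a = random_adjacency(rng, 10)
        assert np.allclose(
            topological_overlap(a), tom_triple_loop(a), atol=1e-12
        )

    def test_rejects_asymmetric_input(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(a)


class TestModuleDetection:
    def test_two_perfect_blocks(self):
        # dissimilarity 0 within blocks, ~1 between: exact recovery
        n = 8
        tom = np.zeros((2 * n, 2 * n))
        tom[:n, :n] = 1.0
        tom[n:, n:] = 1.0
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i}" for i in range(2 * n)]
        cfg = PipelineConfig(min_module_size=3)
        module_of = detect_modules(tom, genes, cfg)
        mods = {module_of[g] for g in genes}
        assert mods == {"M1", "M2"}
        assert len({module_of[g] for g in genes[:n]}) == 1
        assert len({module_of[g] for g in genes[n:]}) == 1

    def test_cut_height_zero_makes_everything_grey(self):
        rng = np.random.default_rng(3)
        a = random_adjacency(rng, 12)
        tom = topological_overlap(a)
        cfg = PipelineConfig(cut_height=0.0, min_module_size=2)
        module_of = detect_modules(tom, [f"g{i}" for i in range(12)], cfg)
        assert set(module_of.values()) == {GREY}

    def test_gene_order_permutation_invariance(self):
        expr, _ = simulate_expression(SimulationPlan(seed=6))
        cfg = PipelineConfig()
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.matrix.shape[0])
        shuffled = ExpressionDataset(
            matrix=expr.matrix.iloc[perm], trait=expr.trait
        )
        m1 = build_network(expr, cfg).module_of
        m2 = build_network(shuffled, cfg).module_of
        # same partition up to label names
        genes = list(expr.matrix.index)
        relabel = {}
        for g in genes:
            relabel.setdefault(m1[g], set()).add(m2[g])
        assert all(len(v) == 1 for v in relabel.values())
        assert len({next(iter(v)) for v in relabel.values()}) == len(relabel)


class TestEigengene:
    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 8))
        expr = dataset(x)
        me = module_eigengene(expr, ["g1"])
        prof = (x[1] - x[1].mean()) / x[1].std(ddof=1)
        assert np.allclose(me, prof)

    def test_identical_genes_share_the_profile(self):
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.vstack([base] * 4)
        me = module_eigengene(dataset(x), [f"g{i}" for i in range(4)])
        prof = (base - base.mean()) / base.std(ddof=1)
        assert np.allclose(me, prof)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 10))
        expr = dataset(x)
        me = module_eigengene(expr, expr.gene_ids)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(
            axis=1, ddof=1, keepdims=True
        )
        evals, evecs = np.linalg.eigh(z.T @ z)
        pc1 = evecs[:, np.argmax(evals)]
        r = np.corrcoef(me, pc1)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_unit_variance_and_sign_convention(self):
        expr, labels = simulate_expression(SimulationPlan(seed=12))
        genes = [g for g, m in labels.items() if m == "M1"]
        me = module_eigengene(expr, genes)
        assert me.std(ddof=1) == pytest.approx(1.0)
        mean_expr = (
            expr.matrix.loc[genes]
            .apply(lambda row: (row - row.mean()) / row.std(ddof=1), axis=1)
            .mean(axis=0)
        )
        assert np.corrcoef(me, mean_expr)[0, 1] > 0


class TestModuleTrait:
    def me_with_exact_r(self, r, trait):
        t = np.asarray(trait, dtype=float)
        u = t - t.mean()
        v = np.array([1.0, -1.0, 0.0, -1.0, 1.0, 0.0])
        assert abs(v @ u) < 1e-12 and abs(v.sum()) < 1e-12
        return r * u / np.linalg.norm(u) + np.sqrt(1 - r * r) * v / np.linalg.norm(v)

    def test_r_093_n6_gives_p_0007(self):
        trait = np.array([0, 0, 0, 1, 1, 1])
        me = self.me_with_exact_r(0.93, trait)
        r, p = module_trait_correlation(me, trait)
        assert r == pytest.approx(0.93, abs=1e-12)
        assert round(p, 3) == 0.007

    def test_r_085_n6_gives_p_003(self):
        trait = np.array([0, 0, 0, 1, 1, 1])
        me = self.me_with_exact_r(0.85, trait)
        _, p = module_trait_correlation(me, trait)
        assert round(p, 2) == 0.03

    def test_zero_correlation_gives_p_one(self):
        trait = np.array([0, 0, 0, 1, 1, 1])
        me = self.me_with_exact_r(0.0, trait)
        r, p = module_trait_correlation(me, trait)
        assert abs(r) < 1e-12
        assert p == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        with pytest.raises(ExpressionError):
            module_trait_correlation(np.arange(6.0), np.ones(6))

    def test_p_matches_numerical_t_integration(self):
        # independent oracle: numerically integrate the t density
        from scipy.integrate import quad
        from scipy.stats import t as tdist

        n = 6
        for r in (0.3, 0.6, 0.93):
            t_stat = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            tail, _ = quad(
                lambda x: tdist.pdf(x, df=n - 2), t_stat, np.inf
            )
            assert correlation_p_value(r, n) == pytest.approx(
                2 * tail, abs=1e-8
            )


class TestKME:
    def test_gene_identical_to_eigengene(self):
        rng = np.random.default_rng(10)
        me = rng.normal(size=8)
        x = np.vstack([me, rng.normal(size=8)])
        expr = dataset(x)
        eg = pd.DataFrame({"M1": me}, index=expr.sample_ids)
        kme = kme_table(expr, eg)
        assert kme.loc["g0", "M1"] == pytest.approx(1.0)

    def test_anticorrelated_gene_gets_minus_one(self):
        rng = np.random.default_rng(10)
        me = rng.normal(size=8)
        x = np.vstack([-me])
        expr = dataset(x)
        eg = pd.DataFrame({"M1": me}, index=expr.sample_ids)
        kme = kme_table(expr, eg)
        assert kme.loc["g0", "M1"] == pytest.approx(-1.0)

    def test_own_module_membership_dominates(self, network_model, expression_fixture):
        _, labels = expression_fixture
        kme = network_model.kme
        n_total, n_good = 0, 0
        for g, m in network_model.module_of.items():
            if m == GREY or kme.shape[1] < 2:
                continue
            n_total += 1
            own = abs(kme.loc[g, m])
            cross = kme.loc[g].drop(m).abs().max()
            n_good += own > cross
        assert n_total > 0
        assert n_good / n_total >= 0.95
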