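"""Demixing tests: marginalization identities, the greedy demixed fit, PCA
comparison, dimensionality selection, and the feasibility eigenproblem."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cispop.containers import SEG_MOVE, SEG_TARGET, LabeledDataMatrix
from cispop.demix import (
    classify_components,
    compare_decompositions,
    demixing_feasibility,
    fit_dpca,
    fit_pca,
    marginal_variance,
    marginalize,
    select_dimensionality,
)
from cispop.synthgen import CounterexampleSpec, make_counterexample


def _matrix_from_tensor(tensor):
    """LabeledDataMatrix from a (C, T, n) array (no normalization)."""
    C, T, n = tensor.shape
    t_axis = np.arange(T, dtype=float) * 10.0 - 200.0
    return LabeledDataMatrix(
        R=tensor.reshape(C * T, n),
        condition=np.repeat(np.arange(C), T),
        time=np.tile(t_axis, C),
        segment=np.tile(np.full(T, SEG_MOVE, np.int8), C),
        norm_range=np.zeros(n),
        norm_const=1.0,
        unit_mean=tensor.reshape(-1, n).mean(axis=0),
    )


class TestMarginalize:
    def test_identical_conditions_have_zero_condition_part(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 20, 5))
        dm = _matrix_from_tensor(np.tile(base, (4, 1, 1)))
        _, R_cond = marginalize(dm)
        assert np.max(np.abs(R_cond)) < 1e-12

    def test_zero_condition_mean_gives_zero_time_part(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 20, 5))
        x -= x.mean(axis=0, keepdims=True)
        dm = _matrix_from_tensor(x)
        R_time, _ = marginalize(dm)
        assert np.max(np.abs(R_time)) < 1e-12

    @given(seed=st.integers(0, 100))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_pythagoras(self, seed):
        rng = np.random.default_rng(seed)
        dm = _matrix_from_tensor(rng.normal(size=(5, 12, 7)))
        R_time, R_cond = marginalize(dm)
        Rc = dm.R - dm.R.mean(axis=0)
        lhs = np.sum(Rc**2)
        rhs = np.sum(R_time**2) + np.sum(R_cond**2)
        assert abs(lhs - rhs) <= 1e-9 * max(lhs, 1.0)
        assert np.allclose(R_time + R_cond, Rc)


class TestMarginalVariance:
    def test_condition_invariant_component(self):
        x = np.tile(np.sin(np.linspace(0, 6, 50)), (4, 1))
        f_ci, f_cs = marginal_variance(x)
        assert abs(f_ci - 1.0) < 1e-12

    def test_sign_balanced_component_is_pure_condition(self):
        s = np.sin(np.linspace(0, 6, 50))
        x = np.stack([s, s, -s, -s])
        f_ci, _ = marginal_variance(x)
        assert abs(f_ci) < 1e-12

    def test_counterexample_matches_brute_force_anova(self):
        comp = make_counterexample(CounterexampleSpec(g=(1.0, 3.0), h=(1.0, 1.0), T=80))
        x = comp.x[0]
        f_ci, _ = marginal_variance(x)
        # brute-force two-way decomposition by direct summation
        xc = x - x.mean()
        C, T = x.shape
        ci_part = sum(C * xc[:, t].mean() ** 2 for t in range(T))
        total = sum(xc[c, t] ** 2 for c in range(C) for t in range(T))
        assert abs(f_ci - ci_part / total) < 1e-9

    def test_all_zero_flagged(self):
        f_ci, f_cs = marginal_variance(np.zeros((3, 10)))
        assert np.isnan(f_ci) and np.isnan(f_cs)


def _planted_matrix(n=20, C=6, T=40, seed=0, noise=0.0):
    """One CI component + CS components with orthogonal unit loadings."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, T)
    ci = 1.0 / (1.0 + np.exp(-(t - 0.6) * 20))  # (T,)
    a1 = rng.normal(size=C)
    a2 = rng.normal(size=C)
    a1 -= a1.mean()  # tuned amplitudes carry no net across-condition mean
    a2 -= a2.mean()
    cs1 = a1[:, None] * np.sin(2 * np.pi * 2 * t)[None, :]
    cs2 = a2[:, None] * np.cos(2 * np.pi * 2 * t)[None, :]
    P = np.linalg.qr(rng.normal(size=(n, 3)))[0]  # orthonormal loadings
    tensor = (np.tile(ci, (C, 1))[:, :, None] * P[:, 0][None, None, :]
              + cs1[:, :, None] * P[:, 1][None, None, :]
              + cs2[:, :, None] * P[:, 2][None, None, :])
    if noise:
        tensor = tensor + noise * rng.normal(size=tensor.shape)
    return _matrix_from_tensor(tensor), P


class TestFitDpca:
    def test_recovers_planted_ci_loading(self):
        dm, P = _planted_matrix()
        dec = fit_dpca(dm, 3)
        k = dec.cis1
        angle = np.arccos(min(1.0, abs(dec.W[:, k] @ P[:, 0])))
        assert angle < 1e-3

    def test_zero_condition_marginal_reduces_to_pca_of_time(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(1, 30, 8))
        dm = _matrix_from_tensor(np.tile(base, (5, 1, 1)))
        dec = fit_dpca(dm, 4)
        assert all(lbl == "time" for lbl in dec.fit_labels)
        pca = fit_pca(dm, 4)
        for k in range(4):
            assert abs(abs(dec.W[:, k] @ pca.W[:, k]) - 1.0) < 1e-6

    def test_components_strictly_classified(self, noiseless_dec):
        assert np.all((noiseless_dec.f_ci > 0.5) | (noiseless_dec.f_cs > 0.5))
        assert not np.any(np.isclose(noiseless_dec.f_ci, 0.5))

    def test_orthonormality(self, noiseless_dec):
        D = noiseless_dec.n_components
        assert np.max(np.abs(noiseless_dec.W.T @ noiseless_dec.W - np.eye(D))) < 1e-8

    def test_rank_exceeded_errors(self):
        dm, _ = _planted_matrix(n=6, C=2, T=5)
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_dpca(dm, 6)  # rank is 3


class TestClassify:
    def test_boundary_is_condition_specific(self, noiseless_dec):
        import copy

        dec = copy.copy(noiseless_dec)
        dec.f_ci = np.array([0.94, 0.5, 0.2])
        ci, cs = classify_components(dec)
        assert ci == [0] and cs == [1, 2]


class TestSelectDimensionality:
    def test_pure_cs_data_needs_exactly_target(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 30, 10))
        x -= x.mean(axis=0, keepdims=True)  # no condition-invariant content
        dm = _matrix_from_tensor(x)
        D, dec = select_dimensionality(dm, target_cs=3)
        assert D == 3
        assert dec.ci_indices.size == 0

    def test_default_population_yields_ten_dims_two_ci(self, noiseless_dm):
        D, dec = select_dimensionality(noiseless_dm, target_cs=8)
        assert D == 10
        assert dec.ci_indices.size == 2

    def test_cs_count_monotone_in_dimensionality(self, noiseless_dm):
        counts = []
        for D in range(8, 15):
            dec = fit_dpca(noiseless_dm, D)
            counts.append(dec.cs_indices.size)
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPca:
    def test_rank_one_capture(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        v = rng.normal(size=5)
        dm = _matrix_from_tensor(np.outer(u, v).reshape(3, 10, 5))
        pca = fit_pca(dm, 1)
        Rc = dm.R - dm.R.mean(axis=0)
        assert pca.variance.sum() / Rc.var(axis=0).sum() > 1.0 - 1e-9

    def test_pca_captures_at_least_dpca_variance(self, noiseless_dm, noiseless_dec):
        pca = fit_pca(noiseless_dm, noiseless_dec.n_components)
        assert pca.variance.sum() >= noiseless_dec.variance.sum() - 1e-9

    def test_variance_ratio_two_routes(self, noiseless_dm, noiseless_dec):
        pca = fit_pca(noiseless_dm, noiseless_dec.n_components)
        ratio, _ = compare_decompositions(noiseless_dec, pca)
        Rc = noiseless_dm.R - noiseless_dm.R.mean(axis=0)
        ratio2 = (np.sum((Rc @ noiseless_dec.W) ** 2)
                  / np.sum((Rc @ pca.W) ** 2))
        assert abs(ratio - ratio2) < 1e-9


class TestCompareDecompositions:
    def test_identical_and_orthogonal(self, noiseless_dm):
        pca = fit_pca(noiseless_dm, 4)
        ratio, angle = compare_decompositions(pca, pca)
        assert ratio == pytest.approx(1.0) and angle == pytest.approx(0.0)
        import copy

        other = copy.copy(pca)
        W = pca.W.copy()
        W[:, [0, 1]] = W[:, [1, 0]]
        other.W = W
        _, angle = compare_decompositions(other, pca)
        assert angle == pytest.approx(90.0)


class TestFeasibility:
    def test_counterexample_matches_grid_search(self):
        comp = make_counterexample(CounterexampleSpec(g=(1.0, 2.0), h=(2.0, 1.0), T=100))
        res = demixing_feasibility(comp)
        assert res.best_purity < 1.0 - 1e-6
        thetas = np.linspace(0.0, np.pi, 10000, endpoint=False)
        best = 0.0
        for th in thetas:
            y = np.cos(th) * comp.x[0] + np.sin(th) * comp.x[1]
            f_ci, _ = marginal_variance(y)
            best = max(best, f_ci)
        assert abs(res.best_purity - best) < 1e-6

    def test_single_time_point_two_components_solvable(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 2, 1))  # D=2, C=2, T=1: (C-1)T = 1 <= D
        res = demixing_feasibility(x)
        assert not res.counting_unsolvable
        # one equation, two unknowns: an exact solution exists generically
        assert res.solvable

    def test_invariant_component_has_unit_purity(self):
        x = np.tile(np.sin(np.linspace(0, 5, 30)), (4, 1))[None]
        res = demixing_feasibility(x)
        assert res.best_purity > 1.0 - 1e-9

    def test_counting_rule_against_brute_force(self):
        """(C-1)T > D iff the difference system generically lacks a null
        space, verified by explicit rank computation on tiny instances."""
        rng = np.random.default_rng(0)
        for C in (2, 3):
            for T in (1, 2, 3):
                for D in (1, 2, 3, 4):
                    x = rng.normal(size=(D, C, T))
                    rows = np.concatenate(
                        [(x[:, c, :] - x[:, c + 1, :]) for c in range(C - 1)],
                        axis=1)  # (D, (C-1)T)
                    exact_solvable = (np.linalg.matrix_rank(rows.T) < D)
                    res = demixing_feasibility(x)
                    assert res.counting_unsolvable == ((C - 1) * T > D)
                    # more equations than unknowns: generically unsolvable
                    if res.counting_unsolvable:
                        assert not exact_solvable
                    # strictly fewer equations than unknowns: solvable
                    if (C - 1) * T < D:
                        assert exact_solvable
                    assert res.solvable == exact_solvable

    def test_degenerate_components_rejected(self):
        with pytest.raises(ValueError):
            demixing_feasibility(np.zeros((2, 3, 4)))


class TestConservation:
    def test_full_rank_variance_conservation(self):
        rng = np.random.default_rng(9)
        dm = _matrix_from_tensor(rng.normal(size=(5, 20, 8)))
        pca = fit_pca(dm, 8)
        Rc = dm.R - dm.R.mean(axis=0)
        total = Rc.var(axis=0).sum()
        assert abs(pca.variance.sum() - total) <= 1e-6 * total

    def test_f_ci_f_cs_sum_to_one(self, noiseless_dec):
        assert np.allclose(noiseless_dec.f_ci + noiseless_dec.f_cs, 1.0, atol=1e-9)
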