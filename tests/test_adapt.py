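"""Joint-distribution adaptation: scatter, MMD operators, eigensolve,
prototype pseudo-labeling and the incremental selection schedule."""

import math

import numpy as np
import pytest
import scipy.linalg

from conftest import random_spd
from dsktl.exceptions import InvalidInputError
from dsktl.mefs import build_graph_laplacian
from dsktl.adapt import (
    AdaptConfig,
    AdaptOperators,
    assemble_operators,
    build_label_matrices,
    build_scatter_matrices,
    centering_matrix,
    class_prototypes,
    fit_dsktl_binary,
    pseudo_label_probabilities,
    select_pseudo_labels,
    solve_transform,
)
from dsktl.spd import FeatureSet


def two_domain_features(seed=0, n=40, q=5, sep=1.0, noise=0.3):
    r = np.random.default_rng(seed)
    y = np.repeat([1, 2], n // 2)
    x = r.standard_normal((n, q)) * noise
    x[:, 0] += np.where(y == 1, sep, -sep)
    xt = r.standard_normal((n, q)) * noise
    xt[:, 0] += np.where(y == 1, sep, -sep)
    return FeatureSet(x, labels=y), FeatureSet(xt), y


class TestScatterMatrices:
    def test_within_zero_when_samples_equal_class_mean(self):
        x = np.array([[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3)
        y = np.repeat([1, 2], 3)
        s_w, s_b = build_scatter_matrices(FeatureSet(x, labels=y))
        np.testing.assert_allclose(s_w, 0.0, atol=1e-12)
        assert np.trace(s_b) > 0

    def test_brute_force_oracle(self, rng):
        x = rng.standard_normal((10, 3))
        y = np.array([1, 1, 1, 1, 2, 2, 2, 1, 2, 2])
        s_w, s_b = build_scatter_matrices(FeatureSet(x, labels=y))
        sw_ref = np.zeros((3, 3))
        sb_ref = np.zeros((3, 3))
        m = x.mean(0)
        for c in (1, 2):
            xc = x[y == c]
            mc = xc.mean(0)
            for row in xc:
                sw_ref += np.outer(row - mc, row - mc)
            sb_ref += len(xc) * np.outer(mc - m, mc - m)
        np.testing.assert_allclose(s_w, sw_ref, atol=1e-10)
        np.testing.assert_allclose(s_b, sb_ref, atol=1e-10)

    def test_psd(self, rng):
        x = rng.standard_normal((20, 4))
        y = np.repeat([1, 2], 10)
        s_w, s_b = build_scatter_matrices(FeatureSet(x, labels=y))
        assert np.linalg.eigvalsh(s_w)[0] >= -1e-10
        assert np.linalg.eigvalsh(s_b)[0] >= -1e-10

    def test_single_class_rejected(self, rng):
        f = FeatureSet(rng.standard_normal((5, 2)), labels=np.ones(5, dtype=int))
        with pytest.raises(InvalidInputError):
            build_scatter_matrices(f)


class TestLabelMatrices:
    def test_balanced_columns(self):
        y_s = np.array([1, 1, 2, 2])
        lm = build_label_matrices(y_s, np.array([1, 2, 1, 2]))
        np.testing.assert_allclose(lm.P_s[:, 0], [0.5, 0.5, 0.0, 0.0])
        np.testing.assert_allclose(lm.P_s[:, 1], [0.0, 0.0, 0.5, 0.5])
        assert lm.Q_s.shape[1] == 2  # C(C-1) ordered pairs for C = 2

    def test_columns_sum_to_one_over_selected(self):
        y_t = np.array([1, 1, 2, 2, 1])
        lm = build_label_matrices(np.array([1, 2]), y_t, selected=np.array([0, 2, 4]))
        np.testing.assert_allclose(lm.P_t.sum(0), [1.0, 1.0])
        assert lm.P_t[1, 0] == 0.0  # unselected row stays zero

    def test_missing_selected_class_gives_zero_column(self):
        lm = build_label_matrices(
            np.array([1, 2]), np.array([1, 1, 1]), selected=np.array([0, 1])
        )
        np.testing.assert_allclose(lm.P_t[:, 1], 0.0)

    def test_transferability_vanishes_for_identical_domains(self, rng):
        x = rng.standard_normal((8, 3))
        y = np.repeat([1, 2], 4)
        lm = build_label_matrices(y, y)
        omega = rng.standard_normal((3, 2))
        src = omega.T @ x.T @ lm.P_s
        tgt = omega.T @ x.T @ lm.P_t
        assert np.linalg.norm(src - tgt) < 1e-12

    def test_invalid_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            build_label_matrices(np.array([1, 3]), np.array([1, 1]), classes=np.array([1, 2]))


class TestAssembleAndSolve:
    def _setup(self, seed=0):
        f_s, f_t, y_truth = two_domain_features(seed)
        y_s = f_s.labels
        s_w, s_b = build_scatter_matrices(f_s)
        graph = build_graph_laplacian(f_t)
        lm = build_label_matrices(y_s, y_truth)
        lam, eta, mu, sigma = 0.3, 0.05, 0.1, 0.7
        ops = assemble_operators(f_s, f_t, lm, s_w, s_b, graph, lam, eta, mu, sigma)
        return f_s, f_t, lm, s_w, s_b, graph, ops

    def test_centering_annihilates_constants(self):
        h = centering_matrix(7)
        np.testing.assert_allclose(h @ np.ones(7), 0.0, atol=1e-12)
        np.testing.assert_allclose(h @ h, h, atol=1e-10)

    def test_operators_symmetric(self):
        *_, ops = self._setup()
        np.testing.assert_allclose(ops.G, ops.G.T, atol=1e-12)
        np.testing.assert_allclose(ops.E, ops.E.T, atol=1e-12)

    def test_quadratic_form_matches_term_by_term_objective(self, rng):
        """ωᵀGω must reproduce the direct per-class evaluation of the full
        adaptation objective: same-class MMD − λ·cross-class MMD + the three
        regularizers."""
        f_s, f_t, lm, s_w, s_b, graph, ops = self._setup()
        q = f_s.dim
        fs, ft = f_s.features.T, f_t.features.T
        y_s = f_s.labels
        y_t = np.repeat([1, 2], f_t.n // 2)
        lam, eta, mu, sigma = ops.lam, ops.eta, ops.mu, ops.sigma
        for _ in range(3):
            omega = rng.standard_normal((2 * q, 2))
            ws, wt = omega[:q], omega[q:]
            direct = 0.0
            for c in (1, 2):
                mu_s = fs[:, y_s == c].mean(axis=1)
                mu_t = ft[:, y_t == c].mean(axis=1)
                direct += np.linalg.norm(ws.T @ mu_s - wt.T @ mu_t) ** 2
                c2 = 2 if c == 1 else 1
                mu_t2 = ft[:, y_t == c2].mean(axis=1)
                direct -= lam * np.linalg.norm(ws.T @ mu_s - wt.T @ mu_t2) ** 2
            direct += eta * np.trace(ws.T @ s_w @ ws)
            direct += mu * np.trace(
                wt.T @ ft @ graph.normalized_laplacian @ ft.T @ wt
            )
            direct += sigma * (
                np.linalg.norm(wt - ws, "fro") ** 2 + np.linalg.norm(wt, "fro") ** 2
            )
            quad = float(np.trace(omega.T @ ops.G @ omega))
            assert quad == pytest.approx(direct, abs=1e-8 * max(1.0, abs(direct)))

    def test_sigma_coupling_with_equal_blocks(self, rng):
        """With ω_s = ω_t only the ‖ω_t‖² part of the coupling survives."""
        q = 4
        coupling = np.block(
            [[np.eye(q), -np.eye(q)], [-np.eye(q), 2 * np.eye(q)]]
        )
        w = rng.standard_normal((q, 3))
        omega = np.vstack([w, w])
        val = np.trace(omega.T @ coupling @ omega)
        assert val == pytest.approx(np.linalg.norm(w, "fro") ** 2, abs=1e-10)

    def _full_rank_ops(self, rng, dim=8):
        g = rng.standard_normal((dim, dim))
        g = 0.5 * (g + g.T)
        e = random_spd(rng, dim)
        zeros = np.zeros((dim // 2, dim // 2))
        return AdaptOperators(G=g, E=e, A_min=zeros, A_max=zeros, S_w=zeros,
                              S_b=zeros, H=zeros, lam=0, eta=0, mu=0, sigma=0)

    def test_eigensolve_residuals_and_orthonormality(self, rng):
        ops = self._full_rank_ops(rng)
        ridge = 1e-8 * np.trace(ops.E) / 8
        omega, vals = solve_transform(ops, 4, ridge=ridge)
        e_reg = ops.E + ridge * np.eye(8)
        for j in range(4):
            lhs = ops.G @ omega[:, j]
            rhs = vals[j] * e_reg @ omega[:, j]
            assert np.linalg.norm(lhs - rhs) < 1e-6 * max(np.linalg.norm(lhs), 1e-12)
        np.testing.assert_allclose(omega.T @ e_reg @ omega, np.eye(4), atol=1e-8)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_identity_pencil_degenerate(self):
        dim = 6
        zeros = np.zeros((3, 3))
        ops = AdaptOperators(G=np.eye(dim), E=np.eye(dim), A_min=zeros,
                             A_max=zeros, S_w=zeros, S_b=zeros, H=zeros,
                             lam=0, eta=0, mu=0, sigma=0)
        _, vals = solve_transform(ops, 3, ridge=0.0)
        np.testing.assert_allclose(vals, 1.0, atol=1e-10)

    def test_returned_transform_beats_random_competitors(self, rng):
        """The minimizing eigenvectors must attain a lower objective than
        E-orthonormalized random subspaces (20 draws)."""
        ops = self._full_rank_ops(rng)
        omega, _ = solve_transform(ops, 3, ridge=0.0)
        ours = np.trace(omega.T @ ops.G @ omega)
        chol = np.linalg.cholesky(ops.E)
        for _ in range(20):
            m = rng.standard_normal((8, 3))
            q_mat, _ = np.linalg.qr(m)
            r = scipy.linalg.solve_triangular(chol.T, q_mat)
            val = np.trace(r.T @ ops.G @ r)
            assert ours <= val + 1e-9

    def test_z_out_of_range_rejected(self, rng):
        ops = self._full_rank_ops(rng)
        with pytest.raises(InvalidInputError):
            solve_transform(ops, 9)


class TestPrototypesAndProbabilities:
    def test_prototype_is_class_mean(self):
        u = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        y = np.array([1, 1, 2])
        protos = class_prototypes(u, y)
        np.testing.assert_allclose(protos, [[1.0, 1.0], [5.0, 5.0]])

    def test_brute_force_indicator_mean(self, rng):
        u = rng.standard_normal((12, 3))
        y = rng.integers(1, 3, 12)
        while len(np.unique(y)) < 2:
            y = rng.integers(1, 3, 12)
        protos = class_prototypes(u, y)
        for j, c in enumerate(np.unique(y)):
            ind = (y == c).astype(float)
            np.testing.assert_allclose(protos[j], (u * ind[:, None]).sum(0) / ind.sum())

    def test_equidistant_sample_uniform_probability(self):
        protos = np.array([[1.0, 0.0], [-1.0, 0.0]])
        probs, labels = pseudo_label_probabilities(np.array([[0.0, 5.0]]), protos)
        np.testing.assert_allclose(probs, [[0.5, 0.5]], atol=1e-12)
        assert labels[0] == 1  # tie resolved to the lower class index

    def test_known_distance_ratio(self):
        # distances 0 and ln 3 give posteriors (0.75, 0.25)
        protos = np.array([[0.0], [np.log(3.0)]])
        probs, labels = pseudo_label_probabilities(np.array([[0.0]]), protos)
        np.testing.assert_allclose(probs, [[0.75, 0.25]], atol=1e-12)
        assert labels[0] == 1

    def test_rows_sum_to_one(self, rng):
        protos = rng.standard_normal((2, 4))
        probs, labels = pseudo_label_probabilities(rng.standard_normal((30, 4)), protos)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(labels, np.argmax(probs, axis=1) + 1)

    def test_single_prototype_rejected(self):
        with pytest.raises(InvalidInputError):
            pseudo_label_probabilities(np.zeros((2, 2)), np.zeros((1, 2)))


class TestPseudoLabelSelection:
    def _probs(self, conf):
        conf = np.asarray(conf)
        return np.column_stack([conf, 1.0 - conf])

    def test_final_iteration_selects_all(self):
        n_c = {1: 10, 2: 10}
        y = np.repeat([1, 2], 10)
        probs = self._probs(np.where(y == 1, 0.9, 0.1))
        sel = select_pseudo_labels(probs, y, 5, 5, n_c, classes=np.array([1, 2]))
        assert sel.size == 20

    def test_first_iteration_quota(self):
        y = np.repeat([1, 2], 10)
        probs = self._probs(np.where(y == 1, 0.9, 0.1))
        sel = select_pseudo_labels(probs, y, 1, 5, {1: 10, 2: 10}, np.array([1, 2]))
        assert sel.size == 4  # ceil(1*10/5) per class

    def test_schedule_counts_formula(self):
        y = np.repeat([1, 2], [13, 7])
        r = np.random.default_rng(0)
        probs = self._probs(np.clip(np.where(y == 1, 0.8, 0.2) + 0.05 * r.standard_normal(20), 0, 1))
        counts = {1: 13, 2: 7}
        t = 4
        for i in range(1, t + 1):
            sel = select_pseudo_labels(probs, y, i, t, counts, np.array([1, 2]))
            expected = math.ceil(i * 13 / t) + math.ceil(i * 7 / t)
            assert sel.size == expected

    def test_tie_broken_by_lower_index(self):
        y = np.array([1, 1, 1])
        probs = self._probs([0.9, 0.8, 0.8])
        sel = select_pseudo_labels(probs, y, 1, 3, {1: 3, 2: 0}, np.array([1, 2]))
        # quota ceil(3/3)=1 -> just the most confident
        assert sel.tolist() == [0]
        sel = select_pseudo_labels(probs, y, 2, 3, {1: 3, 2: 0}, np.array([1, 2]))
        assert sel.tolist() == [0, 1]  # tie between 1 and 2 -> lower index

    def test_shortfall_topped_up_globally(self):
        y = np.array([1, 1, 1, 1])  # argmax pool for class 2 is empty
        probs = self._probs([0.9, 0.8, 0.7, 0.6])
        sel = select_pseudo_labels(probs, y, 2, 2, {1: 2, 2: 2}, np.array([1, 2]))
        assert sel.size == 4


class TestFitBinary:
    def test_identical_domains_no_selection_is_perfect(self):
        cfg = AdaptConfig(z=2, sigma=0.0, eta=0.0, mu=0.0, lam=0.5, T=5,
                          disable_pseudo_selection=True)
        for seed in range(4):
            r = np.random.default_rng(seed)
            n, q = 60, 6
            y = np.repeat([1, 2], n)
            x = r.standard_normal((2 * n, q)) * 0.15
            x[:n, 0] += 1.0
            x[n:, 0] -= 1.0
            res = fit_dsktl_binary(FeatureSet(x, labels=y), FeatureSet(x.copy()), cfg)
            assert np.mean(res.pseudo_labels == y) == 1.0

    def test_identical_domains_full_method_high_accuracy(self):
        cfg = AdaptConfig(z=2, sigma=0.0, eta=0.0, mu=0.0, lam=0.5, T=5)
        r = np.random.default_rng(0)
        n, q = 60, 6
        y = np.repeat([1, 2], n)
        x = r.standard_normal((2 * n, q)) * 0.15
        x[:n, 0] += 1.0
        x[n:, 0] -= 1.0
        res = fit_dsktl_binary(FeatureSet(x, labels=y), FeatureSet(x.copy()), cfg)
        assert np.mean(res.pseudo_labels == y) >= 0.85

    def test_result_invariants(self):
        f_s, f_t, _ = two_domain_features(3)
        cfg = AdaptConfig(z=3, sigma=0.0, eta=0.0, mu=0.0, lam=0.5, T=4)
        res = fit_dsktl_binary(f_s, f_t, cfg)
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(
            res.pseudo_labels, res.classes[np.argmax(res.probabilities, axis=1)]
        )
        assert np.all(np.diff(res.selected_per_iter) >= 0)
        assert res.selected_per_iter[-1] == f_t.n
        assert res.u_t.shape == (f_t.n, 3)
        assert np.all(np.diff(res.eigenvalues) >= -1e-12)

    def test_multiclass_source_rejected(self, rng):
        f_s = FeatureSet(rng.standard_normal((9, 3)), labels=np.repeat([1, 2, 3], 3))
        f_t = FeatureSet(rng.standard_normal((5, 3)))
        with pytest.raises(InvalidInputError):
            fit_dsktl_binary(f_s, f_t)

    def test_z_larger_than_2q_rejected(self):
        f_s, f_t, _ = two_domain_features(0, q=3)
        with pytest.raises(InvalidInputError):
            fit_dsktl_binary(f_s, f_t, AdaptConfig(z=7))

    def test_deterministic(self):
        f_s, f_t, _ = two_domain_features(5)
        cfg = AdaptConfig(z=3, sigma=0.0, eta=0.0, mu=0.0, lam=0.5, T=3)
        r1 = fit_dsktl_binary(f_s, f_t, cfg)
        r2 = fit_dsktl_binary(f_s, f_t, cfg)
        np.testing.assert_array_equal(r1.pseudo_labels, r2.pseudo_labels)
        np.testing.assert_allclose(r1.probabilities, r2.probabilities, atol=0)
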