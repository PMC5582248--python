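"""Cascade estimator: cluster assignment, Lasso path, alternating fit."""

import numpy as np
import pytest

from cascadenet.cascade import (
    CascadeModel,
    TimeClusterAssignment,
    assign_time_clusters,
    fit,
    lagged_views,
    predict,
)
from cascadenet.synthetic import (
    ExpressionCube,
    GeneratorConfig,
    PlantedTruth,
    generate_network,
    simulate_cube,
)


def coordinate_descent_lasso(X, y, alpha, n_iter=2000, tol=1e-12):
    """Brute-force cyclic coordinate descent for
    (1/2n)||y - Xw||^2 + alpha ||w||_1, the oracle for the w-step."""
    n, p = X.shape
    w = np.zeros(p)
    col_sq = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        w_old = w.copy()
        for j in range(p):
            r = y - X @ w + X[:, j] * w[j]
            rho = X[:, j] @ r / n
            if col_sq[j] == 0:
                w[j] = 0.0
                continue
            w[j] = np.sign(rho) * max(abs(rho) - alpha, 0.0) / col_sq[j]
        if np.max(np.abs(w - w_old)) < tol:
            break
    return w


class TestAssignTimeClusters:
    def test_peak_at_second_timepoint_is_cluster_one(self):
        vals = np.zeros((1, 3, 4))
        vals[0, :, 1] = 2.0  # peak at the 2nd timepoint
        cube = ExpressionCube(vals, ("g1",), ("a", "b", "c"), (0, 1, 4, 12))
        assignment = assign_time_clusters(cube, K=3)
        assert assignment.m["g1"] == 1

    def test_noiseless_generator_peaks_recover_planted_clusters(self):
        cfg = GeneratorConfig(edge_density=0.0, noise_sd=0.0, subject_sd=0.0, seed=4)
        truth = generate_network(cfg)
        cube = simulate_cube(truth, cfg)
        est = assign_time_clusters(cube, cfg.n_clusters)
        assert est.m == dict(truth.cluster_of)
        assert not est.flagged

    def test_constant_genes_flagged_into_last_cluster(self):
        vals = np.ones((3, 2, 4))
        cube = ExpressionCube(vals, ("a", "b", "c"), ("s1", "s2"), (0, 1, 4, 12))
        assignment = assign_time_clusters(cube, K=3)
        assert assignment.flagged == {"a", "b", "c"}
        assert all(c == 3 for c in assignment.m.values())

    def test_k_bounds_enforced(self, default_cube):
        with pytest.raises(ValueError):
            assign_time_clusters(default_cube, K=default_cube.n_timepoints)


class TestLaggedViews:
    def test_views_are_shifted_windows_of_the_same_cube(self, default_cube):
        views = lagged_views(default_cube)
        G, P, T = default_cube.values.shape
        assert views.xtilde.shape == (G, P * (T - 1))
        centered = default_cube.values - default_cube.values.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(
            views.xtilde.reshape(G, P, T - 1), centered[:, :, 1:]
        )
        np.testing.assert_allclose(
            views.xhat.reshape(G, P, T - 1), centered[:, :, :-1]
        )


def _single_edge_fixture(n_genes=5, seed=3):
    edges = (("G001", f"G{n_genes:03d}", 1.0),)
    clusters = {f"G{i + 1:03d}": 1 for i in range(n_genes - 1)}
    clusters[f"G{n_genes:03d}"] = 2
    truth = PlantedTruth(edges, clusters, frozenset())
    cfg = GeneratorConfig(
        n_genes=n_genes, n_subjects=6, n_clusters=2, edge_density=0.0,
        noise_sd=0.0, de_fraction=0.0, seed=seed,
    )
    cube = simulate_cube(truth, cfg)
    return truth, cfg, cube, TimeClusterAssignment(clusters, 2)


class TestFit:
    def test_heavy_penalty_shrinks_everything_to_zero(self):
        _, _, cube, clusters = _single_edge_fixture()
        model = fit(cube, clusters, alpha=1e6)
        assert np.all(model.w == 0.0)

    def test_noiseless_single_edge_recovered_by_cv(self):
        truth, _, cube, clusters = _single_edge_fixture()
        model = fit(cube, clusters, cv="loo", seed=0)
        i, j = cube.genes.index("G001"), cube.genes.index("G005")
        assert model.w[i, j] > 0.9
        others = [
            abs(model.w[a, b])
            for a in range(len(cube.genes))
            for b in range(len(cube.genes))
            if (a, b) != (i, j)
        ]
        assert max(others) < 0.05
        # exact least-squares oracle on the one-predictor problem
        views = lagged_views(cube)
        x, y = views.xhat[i], views.xtilde[j]
        ls = float(x @ y / (x @ x))
        assert model.w[i, j] == pytest.approx(ls, abs=0.05)

    def test_objective_trace_non_increasing(self, fitted_model):
        trace = np.asarray(fitted_model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)

    def test_w_step_matches_coordinate_descent_oracle_across_path(self):
        cfg = GeneratorConfig(
            n_genes=10, n_subjects=8, n_clusters=2, edge_density=0.4, seed=6
        )
        truth = generate_network(cfg)
        cube = simulate_cube(truth, cfg)
        clusters = TimeClusterAssignment(dict(truth.cluster_of), 2)
        views = lagged_views(cube)
        gi = {g: k for k, g in enumerate(cube.genes)}
        targets = [g for g in cube.genes if clusters.m[g] == 2]
        cands = [g for g in cube.genes if clusters.m[g] == 1]

        nnz_path = []
        for alpha in [0.001, 0.01, 0.05, 0.1, 0.5, 1.0]:
            model = fit(cube, clusters, alpha=alpha, standardize=False,
                        update_f=False, max_iter=1)
            nnz = 0
            for tgt in targets:
                X = views.xhat[[gi[c] for c in cands]].T
                y = views.xtilde[gi[tgt]]
                w_ref = coordinate_descent_lasso(X, y, alpha)
                w_fit = np.array([model.w[gi[c], gi[tgt]] for c in cands])
                np.testing.assert_allclose(w_fit, w_ref, atol=1e-5)
                nnz += int(np.sum(w_fit != 0))
            nnz_path.append(nnz)
        assert all(a >= b for a, b in zip(nnz_path, nnz_path[1:]))

    def test_scaling_equivariance_of_the_support(self):
        cfg = GeneratorConfig(
            n_genes=8, n_subjects=6, n_clusters=2, edge_density=0.4, seed=2
        )
        truth = generate_network(cfg)
        cube = simulate_cube(truth, cfg)
        clusters = TimeClusterAssignment(dict(truth.cluster_of), 2)
        c = 3.0
        scaled = ExpressionCube(
            cube.values * c, cube.genes, cube.subjects, cube.timepoints,
            cube.condition_of,
        )
        alpha = 0.05
        m1 = fit(cube, clusters, alpha=alpha, standardize=False,
                 update_f=False, max_iter=1)
        m2 = fit(scaled, clusters, alpha=alpha * c**2, standardize=False,
                 update_f=False, max_iter=1)
        np.testing.assert_allclose(m2.w, m1.w, atol=1e-8)

    def test_cv_support_stable_under_scaling_with_standardization(self):
        cfg = GeneratorConfig(
            n_genes=8, n_subjects=6, n_clusters=2, edge_density=0.4, seed=2
        )
        truth = generate_network(cfg)
        cube = simulate_cube(truth, cfg)
        clusters = TimeClusterAssignment(dict(truth.cluster_of), 2)
        scaled = ExpressionCube(
            cube.values * 4.0, cube.genes, cube.subjects, cube.timepoints,
            cube.condition_of,
        )
        m1 = fit(cube, clusters, cv="loo", seed=0)
        m2 = fit(scaled, clusters, cv="loo", seed=0)
        assert (m1.w != 0).tolist() == (m2.w != 0).tolist()

    def test_forward_structure_enforced_in_model(self, fitted_model):
        m = fitted_model.clusters.m
        for reg, tgt, w in fitted_model.edges():
            assert m[reg] < m[tgt]

    def test_precondition_errors(self, default_cube, default_truth, default_config):
        clusters = TimeClusterAssignment(
            dict(default_truth.cluster_of), default_config.n_clusters
        )
        tiny = ExpressionCube(
            default_cube.values[:, :1, :],
            default_cube.genes,
            default_cube.subjects[:1],
            default_cube.timepoints,
        )
        with pytest.raises(ValueError, match="subjects"):
            fit(tiny, clusters)


class TestPredict:
    def test_zero_weight_model_predicts_zero(self):
        _, _, cube, clusters = _single_edge_fixture()
        model = fit(cube, clusters, alpha=1e6)
        np.testing.assert_array_equal(predict(model, cube), 0.0)

    def test_noiseless_self_consistency(self):
        truth, _, cube, clusters = _single_edge_fixture()
        model = fit(cube, clusters, cv="loo", seed=0)
        pred = predict(model, cube)
        centered = cube.values - model.center[:, None, :]
        j = cube.genes.index("G005")
        np.testing.assert_allclose(pred[j], centered[j, :, 1:], atol=1e-8)

    def test_linearity_doubling_a_weight_doubles_the_prediction(self):
        truth, _, cube, clusters = _single_edge_fixture()
        model = fit(cube, clusters, cv="loo", seed=0)
        doubled = CascadeModel(
            genes=model.genes,
            w=model.w * 2.0,
            F=model.F,
            lambda_n=model.lambda_n,
            sigma2=model.sigma2,
            clusters=model.clusters,
            timepoints=model.timepoints,
            center=model.center,
            scale=model.scale,
        )
        np.testing.assert_allclose(
            predict(doubled, cube), 2.0 * predict(model, cube), atol=1e-12
        )

    def test_gene_set_mismatch_rejected(self, fitted_model):
        bad = ExpressionCube(
            np.zeros((2, 2, 4)), ("x", "y"), ("s1", "s2"), fitted_model.timepoints
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict(fitted_model, bad)
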