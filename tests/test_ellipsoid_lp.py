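import numpy as np
import pytest

import ppianet as pn
from ppianet.affinity import FeatureMatrix
from ppianet.ellipsoid_lp import ClassCenters, UnboundedLPError


def _labels(pattern):
    """SampleLabels from a class-code string like 'aabb'."""
    sample_ids = [f"S{j}" for j in range(len(pattern))]
    classes = []
    for ch in pattern:
        if ch not in classes:
            classes.append(ch)
    return pn.SampleLabels(sample_ids, dict(zip(sample_ids, pattern)), classes)


def _fm(edge_feats, node_feats, form="product"):
    edge_feats = np.asarray(edge_feats, dtype=float)
    node_feats = np.asarray(node_feats, dtype=float)
    m = edge_feats.shape[0] if edge_feats.size else node_feats.shape[0]
    edge_feats = edge_feats.reshape(m, -1)
    node_feats = node_feats.reshape(m, -1)
    return FeatureMatrix(
        sample_ids=[f"S{j}" for j in range(m)],
        edge_features=edge_feats,
        node_features=node_feats,
        edge_index=[(f"u{i}", f"v{i}") for i in range(edge_feats.shape[1])],
        node_index=[f"g{i}" for i in range(node_feats.shape[1])],
        form=form,
    )


class TestClassCenters:
    def test_mean_and_median(self):
        fm = _fm([[2.0], [4.0], [1.0], [2.0], [100.0]], np.zeros((5, 0)))
        labels = _labels("aabbb")
        mean_c = pn.compute_class_centers(fm, labels, "mean")
        assert mean_c.edge_centers[0, 0] == 3.0
        med_c = pn.compute_class_centers(fm, labels, "median")
        assert med_c.edge_centers[1, 0] == 2.0

    def test_matches_per_class_loop(self, rng):
        fm = _fm(rng.lognormal(0, 1, (10, 4)), rng.lognormal(0, 1, (10, 3)))
        labels = _labels("aaabbbbccc")
        centers = pn.compute_class_centers(fm, labels, "mean")
        F = fm.combined()
        for k, cls in enumerate(labels.classes):
            rows = [j for j, ch in enumerate("aaabbbbccc") if ch == cls]
            np.testing.assert_allclose(centers.combined()[k], F[rows].mean(axis=0))

    def test_singleton_class_fatal(self):
        fm = _fm(np.ones((3, 1)), np.zeros((3, 0)))
        with pytest.raises(ValueError, match="centers need >= 2"):
            pn.compute_class_centers(fm, _labels("aab"), "mean")


class TestBuildLP:
    def test_row_and_variable_counts(self, rng):
        # q=1, n=0, c=2, m=4: 4 inside + 4 outside + 2 ordering rows
        fm = _fm(rng.lognormal(0, 1, (4, 1)), np.zeros((4, 0)))
        labels = _labels("aabb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=0.5, C=1.0)
        assert lp.A_ub.shape == (10, lp.n_vars)
        assert lp.n_vars == 1 + 0 + 4 + 8

    def test_inside_row_coefficient_is_squared_deviation(self, rng):
        fm = _fm(rng.lognormal(0, 1, (4, 1)), np.zeros((4, 0)))
        labels = _labels("aabb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=0.5, C=1.0)
        # first inside row is class 'a', sample S0
        expected = (fm.edge_features[0, 0] - centers.edge_centers[0, 0]) ** 2
        assert lp.A_ub[0, 0] == pytest.approx(expected, rel=1e-15)
        assert lp.A_ub[0, lp.col_z1(0)] == -1.0
        assert lp.A_ub[0, lp.col_xi(0, 0)] == -1.0

    def test_matches_independent_nested_loop_assembly(self, rng):
        fm = _fm(rng.lognormal(0, 1, (6, 1)), rng.lognormal(0, 1, (6, 1)))
        labels = _labels("aaabbb")
        centers = pn.compute_class_centers(fm, labels)
        lam, alpha, C = 1.0, 0.7, 2.0
        lp = pn.build_lp(fm, centers, labels, lambda_=lam, alpha=alpha, C=C)

        # independent assembly: explicit loops, dict-of-rows
        F, G = fm.combined(), centers.combined()
        m, p, c = 6, 2, 2
        nv = p + 2 * c + m * c
        col_z1 = lambda k: p + k
        col_z2 = lambda k: p + c + k
        col_xi = lambda j, k: p + 2 * c + j * c + k
        rows = []
        member = [0, 0, 0, 1, 1, 1]
        for k in range(c):
            for j in range(m):
                if member[j] == k:
                    row = np.zeros(nv)
                    for i in range(p):
                        row[i] = (F[j, i] - G[k, i]) ** 2
                    row[col_z1(k)] = -1
                    row[col_xi(j, k)] = -1
                    rows.append(row)
        for k in range(c):
            for j in range(m):
                if member[j] != k:
                    row = np.zeros(nv)
                    for i in range(p):
                        row[i] = -((F[j, i] - G[k, i]) ** 2)
                    row[col_z2(k)] = 1
                    row[col_xi(j, k)] = -1
                    rows.append(row)
        for k in range(c):
            row = np.zeros(nv)
            row[col_z1(k)] = 1
            row[col_z2(k)] = -1
            rows.append(row)
        np.testing.assert_array_equal(lp.A_ub, np.array(rows))
        expected_obj = np.concatenate(
            [[1.0], [lam], [alpha] * c, [-alpha] * c, [C] * (m * c)]
        )
        np.testing.assert_array_equal(lp.objective, expected_obj)

    def test_single_class_fatal(self, rng):
        fm = _fm(rng.lognormal(0, 1, (4, 1)), np.zeros((4, 0)))
        labels = _labels("aaaa")
        centers = ClassCenters(fm.edge_features.mean(0, keepdims=True),
                               np.zeros((1, 0)), "mean")
        with pytest.raises(ValueError, match="at least 2 classes"):
            pn.build_lp(fm, centers, labels)


class TestSolveLP:
    def test_zero_vector_feasible(self, rng):
        fm = _fm(rng.lognormal(0, 1, (4, 1)), np.zeros((4, 0)))
        labels = _labels("aabb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=0.5, C=1.0)
        zero = pn.LPSolution(
            w=np.zeros(1), z1=np.zeros(2), z2=np.zeros(2), xi=np.zeros((4, 2)),
            objective_value=0.0, status="manual",
        )
        pn.verify_solution(lp, zero)  # must not raise

    def test_separated_centers_select_feature_without_slack(self):
        # inside samples sit exactly on centers 0 and 10; with a strong slack
        # penalty the optimum uses the feature (w > 0) and no slack
        fm = _fm([[0.0], [0.0], [10.0], [10.0]], np.zeros((4, 0)))
        labels = _labels("aabb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=1.0, C=1000.0)
        sol = pn.solve_lp(lp)
        assert sol.w[0] > 0
        assert sol.xi.sum() == pytest.approx(0.0, abs=1e-9)

    def test_identical_centers_give_zero_objective(self, rng):
        # no separation to reward: w = 0, z2 = 0 optimal when C*(m - m_k) > alpha
        values = np.tile(rng.lognormal(0, 1, (1, 1)), (6, 1))
        fm = _fm(values, np.zeros((6, 0)))
        labels = _labels("aaabbb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=1.0, C=1.0)  # C*(m-m_k)=3 > 1
        sol = pn.solve_lp(lp)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sol.w, 0) and np.allclose(sol.z2, 0)

    def test_unbounded_cell_raises(self, rng):
        # alpha > C * (m - m_k): growing z2 along the slack ray pays off forever
        fm = _fm(rng.lognormal(0, 1, (4, 1)), np.zeros((4, 0)))
        labels = _labels("aabb")
        centers = pn.compute_class_centers(fm, labels)
        lp = pn.build_lp(fm, centers, labels, alpha=5.0, C=0.1)
        with pytest.raises(UnboundedLPError, match="increase C or decrease alpha"):
            pn.solve_lp(lp)


class TestSelectFeatures:
    def _solution(self, weights):
        w = np.asarray(weights, dtype=float)
        return pn.LPSolution(w=w, z1=np.zeros(2), z2=np.zeros(2),
                             xi=np.zeros((2, 2)), objective_value=0.0, status="manual")

    def _lp(self, q, n):
        return pn.EllipsoidLP(
            objective=None, A_ub=None, b_ub=None, bounds=None,
            q=q, n=n, c=2, m=2, lambda_=1.0, alpha=1.0, C=1.0,
            edge_index=[(f"u{i}", f"v{i}") for i in range(q)],
            node_index=[f"g{i}" for i in range(n)], classes=["a", "b"],
        )

    def test_threshold_rule(self):
        lp = self._lp(3, 0)
        bset = pn.select_features(self._solution([0.5, 1e-6, 0.2]), lp, 1e-4)
        assert [(u, v) for u, v, _ in bset.selected_edges] == [("u0", "v0"), ("u2", "v2")]

    def test_threshold_one_empty(self):
        lp = self._lp(2, 1)
        bset = pn.select_features(self._solution([1.0, 0.3, 0.9]), lp, 1.0)
        assert bset.n_features == 0

    def test_matches_thresholding_oracle_on_planted_run(self, small_data):
        expr, edges, labels, _ = small_data
        bset, fm, lp, sol = pn.select_biomarkers(expr, edges, labels,
                                                 alpha=2.0, C=1.0)
        expected_edges = {lp.edge_index[i] for i in range(lp.q) if sol.w[i] > 1e-4}
        expected_nodes = {lp.node_index[i] for i in range(lp.n) if sol.w[lp.q + i] > 1e-4}
        assert bset.edge_set() == expected_edges
        assert {g for g, _ in bset.selected_nodes} == expected_nodes


class TestSlackMonotonicity:
    def test_total_slack_non_increasing_in_C(self, small_data):
        expr, edges, labels, _ = small_data
        fm = pn.compute_ppia(expr, edges)
        centers = pn.compute_class_centers(fm, labels)
        slacks = []
        for C in (1.0, 10.0, 100.0, 1000.0):
            lp = pn.build_lp(fm, centers, labels, alpha=2.0, C=C)
            sol = pn.solve_lp(lp)
            slacks.append(sol.xi.sum())
        assert all(a >= b - 1e-7 for a, b in zip(slacks, slacks[1:]))


class TestGridSearch:
    def test_singleton_grid_returns_cell(self, small_data):
        expr, edges, labels, _ = small_data
        fm = pn.compute_ppia(expr, edges)
        alpha, C, bset, table = pn.grid_search(
            fm, labels, [2.0], [1.0], cv_scheme="loo", n_trees=30, seed=0
        )
        assert (alpha, C) == (2.0, 1.0) and bset.n_features > 0
        assert len(table) == 1

    def test_matches_exhaustive_reevaluation(self, small_data):
        expr, edges, labels, _ = small_data
        fm = pn.compute_ppia(expr, edges)
        alpha_grid, C_grid = [2.0, 3.0], [1.0, 10.0]
        best_alpha, best_C, best_set, table = pn.grid_search(
            fm, labels, alpha_grid, C_grid, cv_scheme="loo", n_trees=30, seed=0
        )
        # independent re-evaluation of every cell via the low-level operations
        from ppianet.evaluation import cross_validate

        centers = pn.compute_class_centers(fm, labels)
        X = fm.combined()
        cells = []
        for alpha in alpha_grid:
            for C in C_grid:
                lp = pn.build_lp(fm, centers, labels, alpha=alpha, C=C)
                sol = pn.solve_lp(lp)
                cols = np.flatnonzero(sol.w > 1e-4)
                if cols.size == 0:
                    continue
                rep = cross_validate(X[:, cols], labels, scheme="loo",
                                     n_trees=30, seed=0)
                cells.append((-rep.accuracy, cols.size, alpha, C))
        expected = min(cells)
        assert (best_alpha, best_C) == (expected[2], expected[3])
        assert -min(cells)[0] == max(t["accuracy"] for t in table
                                     if t["n_selected"] > 0)

    def test_tie_breaks_toward_fewer_features(self, monkeypatch, small_data):
        expr, edges, labels, _ = small_data
        fm = pn.compute_ppia(expr, edges)
        # force every cell to the same accuracy: the sparser cell must win
        import ppianet.evaluation as ev

        monkeypatch.setattr(
            ev, "cross_validate",
            lambda *a, **k: pn.EvaluationReport(
                accuracy=0.9, scheme="loo", confusion=np.zeros((2, 2)),
                n_features=0, classifier_seed=0,
            ),
        )
        alpha, C, bset, table = pn.grid_search(
            fm, labels, [2.0, 3.0], [1.0], cv_scheme="loo", n_trees=10, seed=0
        )
        sizes = {(t["alpha"], t["C"]): t["n_selected"] for t in table}
        nonzero = {k: v for k, v in sizes.items() if v > 0}
        assert sizes[(alpha, C)] == min(nonzero.values())
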