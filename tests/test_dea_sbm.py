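import numpy as np
import pytest

from thcdea.dea_sbm import (
    DeaProblem,
    sbm_score,
    score_panel,
    super_sbm_score,
    two_stage_score,
)
from thcdea.synthetic_data import DeaGenConfig, generate_dea_panel

from _oracles import sbm_grid_oracle
from conftest import random_dea_problem


class TestSbmScore:
    def test_dominated_unit_closed_form(self, abc_problem):
        # C=(4,2) against frontier {A=(2,2)}: halve the input, no output slack
        X, Y = abc_problem
        sol = sbm_score(DeaProblem(X, Y, evaluated_index=2))
        assert sol.score == pytest.approx(0.5, abs=1e-8)
        assert sol.stage == "sbm"

    def test_self_reference_identity(self):
        sol = sbm_score(DeaProblem([[2.0]], [[2.0]], evaluated_index=0))
        assert sol.score == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(sol.input_slacks, 0, atol=1e-9)
        assert np.allclose(sol.output_slacks, 0, atol=1e-9)

    def test_dominated_units_score_below_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X, Y = random_dea_problem(rng, n=3)
            # make unit 2 strictly dominated by unit 0
            X[:, 2] = X[:, 0] * rng.uniform(1.1, 2.0)
            Y[:, 2] = Y[:, 0] * rng.uniform(0.3, 0.9)
            sol = sbm_score(DeaProblem(X, Y, evaluated_index=2))
            assert sol.score < 1.0

    def test_certificate_reproduces_score(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, Y = random_dea_problem(rng)
            j = int(rng.integers(X.shape[1]))
            sol = sbm_score(DeaProblem(X, Y, evaluated_index=j))
            x0, y0 = X[:, j], Y[:, j]
            # constraints of the envelopment program hold at LP tolerance
            np.testing.assert_allclose(X @ sol.lambdas + sol.input_slacks, x0, atol=1e-6)
            np.testing.assert_allclose(Y @ sol.lambdas - sol.output_slacks, y0, atol=1e-6)
            assert sol.lambdas.sum() == pytest.approx(1.0, abs=1e-8)
            obj = (1 - (sol.input_slacks / x0).mean()) / (1 + (sol.output_slacks / y0).mean())
            assert obj == pytest.approx(sol.score, abs=1e-6)

    def test_matches_grid_oracle_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(2, 5))
            d = int(rng.integers(1, 3))
            X, Y = random_dea_problem(rng, n=n, m=d, s=d)
            j = int(rng.integers(n))
            lp = sbm_score(DeaProblem(X, Y, evaluated_index=j)).score
            oracle = sbm_grid_oracle(X, Y, j)
            assert lp == pytest.approx(oracle, abs=1e-3)

    def test_units_invariance(self):
        # multiplying any input/output row by c > 0 leaves scores unchanged
        rng = np.random.default_rng(7)
        X, Y = random_dea_problem(rng, n=4, m=2, s=2)
        base = [sbm_score(DeaProblem(X, Y, j)).score for j in range(4)]
        Xs = X * np.array([[3.7], [0.2]])
        Ys = Y * np.array([[12.0], [0.05]])
        scaled = [sbm_score(DeaProblem(Xs, Ys, j)).score for j in range(4)]
        np.testing.assert_allclose(scaled, base, atol=1e-7)

    def test_input_increase_never_raises_score(self):
        rng = np.random.default_rng(13)
        X, Y = random_dea_problem(rng, n=4, m=2, s=2)
        j = 1
        s0 = sbm_score(DeaProblem(X, Y, j)).score
        X2 = X.copy()
        X2[:, j] *= 1.5
        s1 = sbm_score(DeaProblem(X2, Y, j)).score
        assert s1 <= s0 + 1e-8


class TestSuperSbm:
    def test_extreme_unit_closed_form(self, abc_problem):
        # A=(2,2) vs {B=(4,4), C=(4,2)}: xbar >= 4, ybar <= 2 -> (4/2)/(2/2) = 2
        X, Y = abc_problem
        sol = super_sbm_score(DeaProblem(X, Y, evaluated_index=0))
        assert sol.score == pytest.approx(2.0, abs=1e-8)
        assert sol.lambdas[0] == 0.0

    def test_interior_point_scores_one(self):
        X = np.array([[2.0, 4.0, 3.0]])
        Y = np.array([[2.0, 4.0, 3.0]])
        sol = super_sbm_score(DeaProblem(X, Y, evaluated_index=2))
        assert sol.score == pytest.approx(1.0, abs=1e-8)

    def test_twin_unit_scores_one(self):
        X = np.array([[2.0, 2.0]])
        Y = np.array([[2.0, 2.0]])
        sol = super_sbm_score(DeaProblem(X, Y, evaluated_index=0))
        assert sol.score == pytest.approx(1.0, abs=1e-8)

    def test_super_score_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, Y = random_dea_problem(rng, n=4)
            sol = super_sbm_score(DeaProblem(X, Y, evaluated_index=0))
            if sol.feasible:
                assert sol.score >= 1.0 - 1e-8

    def test_units_invariance(self):
        rng = np.random.default_rng(9)
        X, Y = random_dea_problem(rng, n=4, m=2, s=2)
        base = super_sbm_score(DeaProblem(X, Y, 0)).score
        scaled = super_sbm_score(
            DeaProblem(X * np.array([[2.0], [9.0]]), Y * np.array([[0.1], [4.0]]), 0)
        ).score
        assert scaled == pytest.approx(base, abs=1e-7)


class TestTwoStage:
    def test_inefficient_branch_returns_sbm(self, abc_problem):
        X, Y = abc_problem
        assert two_stage_score(DeaProblem(X, Y, 2)).stage == "sbm"

    def test_efficient_branch_returns_super(self, abc_problem):
        X, Y = abc_problem
        sol = two_stage_score(DeaProblem(X, Y, 0))
        assert sol.stage == "super_sbm"
        assert sol.score == pytest.approx(2.0, abs=1e-8)

    def test_frontier_panel_all_super(self):
        panel, _ = generate_dea_panel(
            DeaGenConfig(n_units=8, n_periods=2, inefficiency_scale=0.0, seed=2))
        table = score_panel(panel)
        assert (table.scores >= 1.0 - 1e-6).all()
        assert (table.stage != "sbm").all()


class TestScorePanel:
    def test_identical_years_identical_columns(self):
        panel, _ = generate_dea_panel(DeaGenConfig(n_units=6, n_periods=1, seed=4))
        inputs = np.repeat(panel.inputs, 2, axis=2)
        outputs = np.repeat(panel.outputs, 2, axis=2)
        from thcdea.panel_io import PanelDataset

        p2 = PanelDataset(panel.unit_ids, [2012, 2013], inputs, outputs)
        table = score_panel(p2)
        np.testing.assert_allclose(table.scores[:, 0], table.scores[:, 1], atol=1e-9)

    def test_permutation_equivariance(self):
        panel, _ = generate_dea_panel(DeaGenConfig(n_units=6, n_periods=2, seed=8))
        table = score_panel(panel)
        perm = np.array([3, 1, 5, 0, 2, 4])
        from thcdea.panel_io import PanelDataset

        pp = PanelDataset(
            [panel.unit_ids[i] for i in perm],
            panel.period_ids,
            panel.inputs[perm],
            panel.outputs[perm],
        )
        tp = score_panel(pp)
        np.testing.assert_allclose(tp.scores, table.scores[perm], atol=1e-7)

    def test_output_frame_shape_with_means(self):
        panel, _ = generate_dea_panel(DeaGenConfig(n_units=5, n_periods=3, seed=6))
        df = score_panel(panel).to_frame()
        assert df.shape == (6, 4)  # units + Mean row, years + Mean column
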