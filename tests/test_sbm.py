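import numpy as np
import pytest

import effimarkov as em
from effimarkov.sbm import sbm_lp, super_sbm_lp

from oracles import sbm_grid_oracle, super_sbm_grid_oracle

TWO_DMU = (np.array([[1.0], [2.0]]), np.array([[1.0], [1.0]]))


class TestHandExamples:
    def test_dominated_unit_scores_half(self):
        X, Y = TWO_DMU
        rho, s_in, s_out, lam = sbm_lp(X, Y, 1, vrs=True)
        assert rho == pytest.approx(0.5, abs=1e-9)
        assert s_in[0] == pytest.approx(1.0, abs=1e-9)
        assert s_out[0] == pytest.approx(0.0, abs=1e-9)
        assert lam[0] == pytest.approx(1.0, abs=1e-9)

    def test_undominated_unit_is_efficient_with_zero_slacks(self):
        X, Y = TWO_DMU
        rho, s_in, s_out, _ = sbm_lp(X, Y, 0, vrs=True)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert np.abs(s_in).max() < 1e-9 and np.abs(s_out).max() < 1e-9

    def test_duplicate_of_frontier_unit_is_efficient(self):
        X = np.array([[1.0], [1.0], [2.0]])
        Y = np.array([[1.0], [1.0], [1.5]])
        assert sbm_lp(X, Y, 1, vrs=True)[0] == pytest.approx(1.0, abs=1e-9)

    def test_super_efficiency_of_extreme_unit_crs(self):
        X, Y = TWO_DMU
        delta, *_ = super_sbm_lp(X, Y, 0, vrs=False)
        assert delta == pytest.approx(2.0, abs=1e-9)

    def test_super_efficiency_with_duplicate_present(self):
        X = np.array([[1.0], [1.0], [2.0]])
        Y = np.array([[1.0], [1.0], [1.0]])
        delta, *_ = super_sbm_lp(X, Y, 0, vrs=True)
        assert delta == pytest.approx(1.0, abs=1e-9)

    def test_super_efficiency_of_non_extreme_collinear_unit(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Y = np.array([[1.0], [2.0], [3.0]])
        delta, *_ = super_sbm_lp(X, Y, 1, vrs=False)
        assert delta == pytest.approx(1.0, abs=1e-9)


class TestGridOracle:
    """LP optimum vs dense lambda-simplex enumeration on small instances."""

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("vrs", [True, False])
    def test_sbm_matches_grid(self, seed, vrs):
        r = np.random.default_rng(seed)
        n, m, q = 3, 2, 1
        X = r.uniform(1, 5, (n, m))
        Y = r.uniform(1, 5, (n, q))
        for k in range(n):
            lp = sbm_lp(X, Y, k, vrs=vrs)[0]
            grid = sbm_grid_oracle(X, Y, k, vrs=vrs, steps=60)
            assert lp <= grid + 1e-9  # LP is exact, grid an upper bound
            assert lp == pytest.approx(grid, abs=2e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_super_sbm_matches_grid(self, seed):
        r = np.random.default_rng(100 + seed)
        n, m, q = 3, 1, 2
        X = r.uniform(1, 5, (n, m))
        Y = r.uniform(1, 5, (n, q))
        for k in range(n):
            if sbm_lp(X, Y, k, vrs=True)[0] < 1 - 1e-6:
                continue
            lp = super_sbm_lp(X, Y, k, vrs=True)[0]
            grid = super_sbm_grid_oracle(X, Y, k, vrs=True, steps=400)
            assert lp <= grid + 1e-9
            assert lp == pytest.approx(grid, abs=1e-3)


class TestInvariants:
    def _random_instance(self, seed, n=5, m=2, q=2):
        r = np.random.default_rng(seed)
        return r.uniform(1, 10, (n, m)), r.uniform(1, 10, (n, q))

    @pytest.mark.parametrize("seed", range(4))
    def test_units_invariance(self, seed):
        X, Y = self._random_instance(seed)
        base = [sbm_lp(X, Y, k)[0] for k in range(len(X))]
        X2 = X.copy()
        X2[:, 0] *= 37.5  # rescale one input column for every DMU
        Y2 = Y.copy()
        Y2[:, 1] *= 0.04
        scaled = [sbm_lp(X2, Y2, k)[0] for k in range(len(X))]
        np.testing.assert_allclose(base, scaled, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotonic_in_own_input(self, seed):
        X, Y = self._random_instance(seed)
        rho = sbm_lp(X, Y, 0)[0]
        X2 = X.copy()
        X2[0, 0] *= 1.5
        assert sbm_lp(X2, Y, 0)[0] <= rho + 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_score_ranges_and_vrs_convexity(self, seed):
        X, Y = self._random_instance(seed)
        for k in range(len(X)):
            rho, _, _, lam = sbm_lp(X, Y, k, vrs=True)
            assert 0 < rho <= 1 + 1e-9
            assert lam.sum() == pytest.approx(1.0, abs=1e-9)
            assert (lam >= -1e-12).all()
            if rho >= 1 - 1e-6:
                out = super_sbm_lp(X, Y, k, vrs=True)
                assert out is not None
                assert out[0] >= 1 - 1e-9


class TestEfficiencyTable:
    def test_synthetic_frontier_recovered_exactly(self):
        panel, truth = em.gen_dea_panel(
            em.FrontierSpec(n_dmu=6, n_efficient=2, seed=11))
        eff, report = em.efficiency_table(panel)
        flagged = eff.data["rho"] >= 1 - 1e-6
        assert list(flagged) == list(truth["efficient"])
        assert set(report["status"]) <= {"efficient", "inefficient"}

    def test_unit_inefficiency_factors_leave_all_efficient(self):
        # factor exactly 1: every non-frontier unit duplicates its parent
        panel, truth = em.gen_dea_panel(
            em.FrontierSpec(n_dmu=4, n_efficient=2, seed=1,
                            inefficiency_range=(1.0, 1.0)))
        eff, _ = em.efficiency_table(panel)
        assert truth["efficient"].all()
        assert (eff.data["rho"] >= 1 - 1e-6).all()

    def test_input_rescaling_leaves_table_unchanged(self):
        panel, _ = em.gen_dea_panel(
            em.FrontierSpec(n_dmu=5, n_efficient=2, seed=7))
        eff1, _ = em.efficiency_table(panel)
        df = panel.data.copy()
        df[["x1", "x2", "x3"]] *= 10.0
        eff2, _ = em.efficiency_table(em.IndicatorPanel(df))
        np.testing.assert_allclose(eff1.data["rho"], eff2.data["rho"],
                                   atol=1e-8)

    def test_super_score_requires_efficiency(self):
        panel, truth = em.gen_dea_panel(
            em.FrontierSpec(n_dmu=4, n_efficient=1, seed=2))
        loser = truth.loc[~truth["efficient"], "unit"].iloc[0]
        with pytest.raises(ValueError, match="efficient"):
            em.super_sbm_score(panel, loser, 2000)
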