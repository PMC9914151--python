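import numpy as np
import pandas as pd
import pytest

import effimarkov as em

from oracles import absorption_oracle, stationary_eig_oracle


def panel_from_rows(rows, k=4):
    return em.StatePanel(pd.DataFrame(rows, columns=["unit", "year", "state"]),
                         k=k)


class TestTransitionMatrix:
    def test_hand_counted_two_unit_panel(self):
        states = panel_from_rows([
            ("a", 0, 1), ("a", 1, 1), ("a", 2, 2),
            ("b", 0, 2), ("b", 1, 2), ("b", 2, 2),
        ])
        tm = em.transition_matrix(states)
        assert tm.counts[0, :2].tolist() == [1, 1]
        np.testing.assert_allclose(tm.probs[0], [0.5, 0.5, 0, 0])
        np.testing.assert_allclose(tm.probs[1], [0, 1, 0, 0])
        assert tm.origin_totals.tolist() == [2, 2, 0, 0]
        assert tm.undefined_rows == [3, 4]

    def test_constant_states_give_identity_rows(self):
        states = panel_from_rows(
            [(u, y, s) for u, s in [("a", 1), ("b", 3)] for y in range(4)])
        tm = em.transition_matrix(states)
        assert tm.probs[0, 0] == 1.0 and tm.probs[2, 2] == 1.0

    def test_rows_with_mass_are_stochastic(self, study_states):
        tm = em.transition_matrix(study_states)
        nz = tm.origin_totals > 0
        np.testing.assert_allclose(tm.probs[nz].sum(axis=1), 1.0, atol=1e-9)
        assert tm.origin_totals.sum() == 20 * 9

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            em.transition_matrix(panel_from_rows([("a", 0, 1)]))


class TestInitialDistribution:
    def test_constant_panel(self):
        states = panel_from_rows([("a", y, 2) for y in range(5)])
        np.testing.assert_allclose(em.initial_distribution(states),
                                   [0, 1, 0, 0])

    def test_equal_occupancy_by_construction(self):
        rows = [(f"u{s}", y, s) for s in (1, 2, 3, 4) for y in range(3)]
        np.testing.assert_allclose(em.initial_distribution(panel_from_rows(rows)),
                                   [0.25] * 4)


class TestTransitionTypes:
    def test_endpoint_comparison(self, study_states):
        types = em.transition_type_map(study_states, 2010, 2019)
        assert types["Sichuan"] == "upward"
        assert types["Ningxia"] == "unchanged"
        assert sorted(types[types == "downward"].index) == [
            "Gansu", "Guizhou", "Heilongjiang", "Henan",
            "Inner Mongolia", "Qinghai"]

    def test_identical_endpoints_unchanged(self):
        states = panel_from_rows([("a", 0, 2), ("a", 1, 4), ("a", 2, 2)])
        assert em.transition_type_map(states, 0, 2)["a"] == "unchanged"


class TestSpatialLag:
    def test_mutual_neighbors_swap_scores(self):
        amap = em.AdjacencyMap.from_edges([("A", "B")])
        df = pd.DataFrame({
            "unit": ["A", "B"] * 2, "year": [2000, 2000, 2001, 2001],
            "region": "r", "rho": [0.3, 1.5, 0.4, 1.6]})
        lag = em.spatial_lag_values(em.EfficiencyPanel(df), amap)
        assert lag.loc["A", 2000] == 1.5 and lag.loc["B", 2000] == 0.3
        assert lag.loc["A", 2001] == 1.6 and lag.loc["B", 2001] == 0.4

    def test_isolated_unit_raises_for_lag_states(self):
        amap = em.AdjacencyMap.from_edges([("A", "B")], units=["A", "B", "C"])
        df = pd.DataFrame({
            "unit": ["A", "B", "C"] * 2,
            "year": [2000] * 3 + [2001] * 3,
            "region": "r", "rho": [0.5, 1.0, 1.5] * 2})
        with pytest.warns(UserWarning, match="isolated"):
            with pytest.raises(ValueError, match="isolated"):
                em.spatial_lag_states(em.EfficiencyPanel(df), amap,
                                      em.StateBreaks((0.7, 0.9, 1.2)),
                                      classification="shared")

    def test_high_unit_with_low_neighbors_on_study_panel(
            self, study_panel, study_states, study_breaks, contiguity):
        lag = em.spatial_lag_states(study_panel, contiguity, study_breaks)
        own = study_states.pivot().loc["Ningxia"]
        nbr = lag.pivot().loc["Ningxia"]
        assert (own == 4).all() and (nbr <= 2).all()


class TestSpatialTransitionSet:
    def test_counts_conserve_traditional_matrix(self, study_states,
                                                study_spatial):
        total = study_spatial.total_counts()
        np.testing.assert_array_equal(
            total, em.transition_matrix(study_states).counts)

    def test_single_lag_class_reduces_to_traditional(self):
        states = panel_from_rows([
            ("a", 0, 1), ("a", 1, 2), ("b", 0, 2), ("b", 1, 2)])
        lag = panel_from_rows([(u, y, 3) for u in "ab" for y in (0, 1)])
        sts = em.spatial_transition_set(states, lag)
        np.testing.assert_array_equal(
            sts.conditionals[3].counts, em.transition_matrix(states).counts)
        for N in (1, 2, 4):
            assert sts.conditionals[N].counts.sum() == 0

    def test_lag_conditioned_generation_recovers_kernels(self):
        kernels = {
            1: np.array([[.9, .1, 0, 0], [.5, .5, 0, 0],
                         [.1, .4, .5, 0], [0, .2, .4, .4]]),
            2: np.array([[.7, .3, 0, 0], [.2, .6, .2, 0],
                         [0, .1, .8, .1], [0, 0, .3, .7]]),
            3: np.array([[.5, .4, .1, 0], [.1, .6, .3, 0],
                         [0, .05, .85, .1], [0, 0, .2, .8]]),
            4: np.array([[.4, .4, .2, 0], [.1, .5, .4, 0],
                         [0, .05, .75, .2], [0, 0, .1, .9]]),
        }
        graph = em.gen_adjacency(2000, "ring")
        spec = em.ChainSpec(kernels, n_years=60, adjacency=graph, seed=5)
        states, values, lag_states = em.gen_markov_panel(spec)
        sts = em.spatial_transition_set(states, lag_states)
        checked = 0
        for N, truth in kernels.items():
            est = sts.conditionals[N]
            seen = est.origin_totals > 1500
            checked += int(seen.sum())
            err = np.abs(est.probs[seen] - truth[seen]).max()
            assert err < 0.03
        assert checked >= 8  # enough well-populated rows to be meaningful


class TestLimitingDistribution:
    def test_identity_matrix_fixes_any_start(self):
        pi0 = np.array([0.4, 0.3, 0.2, 0.1])
        np.testing.assert_allclose(
            em.limiting_distribution(np.eye(4), pi0), pi0)

    def test_one_step_mixing(self):
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(
            em.limiting_distribution(P, [0.9, 0.1]), [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_power_iteration_matches_eigen_oracle(self, seed):
        r = np.random.default_rng(seed)
        P = r.uniform(0.05, 1, (4, 4))
        P /= P.sum(axis=1, keepdims=True)
        pi = em.limiting_distribution(P, [0.25] * 4, tol=1e-14)
        np.testing.assert_allclose(pi, stationary_eig_oracle(P), atol=1e-10)
        np.testing.assert_allclose(pi, em.stationary_distribution(P),
                                   atol=1e-10)

    def test_reducible_chain_matches_absorption_closed_form(self):
        P = np.array([
            [1.0, 0.0, 0.0],
            [0.3, 0.5, 0.2],
            [0.0, 0.0, 1.0],
        ])
        pi0 = np.array([0.2, 0.6, 0.2])
        lim = em.limiting_distribution(P, pi0, tol=1e-15)
        np.testing.assert_allclose(lim, absorption_oracle(P, pi0, [0, 2]),
                                   atol=1e-12)

    def test_periodic_chain_needs_cesaro(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(RuntimeError, match="[Cc]esaro"):
            em.limiting_distribution(P, [0.8, 0.2], max_iter=500)
        pi = em.limiting_distribution(P, [0.8, 0.2], cesaro=True, tol=1e-9)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-6)

    def test_mass_on_undefined_row_rejected(self):
        P = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            em.limiting_distribution(P, [0.5, 0.5])

    def test_rounded_published_rows_renormalized(self):
        P = em.datasets.reference_spatial_matrices()[3]
        assert P.sum(axis=1).max() > 1  # printed at 4 dp
        pi = em.limiting_distribution(P, [0.25] * 4)
        assert pi.sum() == pytest.approx(1.0, abs=1e-9)


class TestEstimationConsistency:
    def test_large_simulation_recovers_kernel(self):
        P = np.array([[.7, .2, .1, 0], [.1, .6, .2, .1],
                      [0, .2, .7, .1], [.1, .1, .2, .6]])
        spec = em.ChainSpec(P, n_units=2000, n_years=50, seed=42)
        states, _, _ = em.gen_markov_panel(spec)
        est = em.transition_matrix(states)
        assert np.abs(est.probs - P).max() < 0.02
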