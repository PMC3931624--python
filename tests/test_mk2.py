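"""Mk2 transition probabilities, pruning likelihood, ASR and simulation."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (enum_loglik, enum_marginals, random_tree_newick,
                      transition_via_expm)
from pvrda import (Mk2Model, Mk2Rates, ValidationError, fit_rates, loglik,
                   marginal_asr, read_newick, simulate_character)
from pvrda.mk2 import transition_matrix
from pvrda.simulate import simulate_tree


def random_rates(rng):
    return Mk2Rates(float(rng.uniform(0.05, 5)), float(rng.uniform(0.05, 5)))


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_matrix(Mk2Rates(3.0, 0.7), 0.0),
                           np.eye(2))

    def test_long_time_reaches_stationary(self):
        P = transition_matrix(Mk2Rates(1.0, 3.0), 500.0)
        assert np.allclose(P, [[0.75, 0.25], [0.75, 0.25]], atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            transition_matrix(Mk2Rates(1.0, 1.0), -0.1)

    def test_matches_matrix_exponential(self, rng):
        for _ in range(100):
            r = random_rates(rng)
            t = float(rng.uniform(0, 4))
            assert np.abs(transition_matrix(r, t)
                          - transition_via_expm(r, t)).max() < 1e-10

    def test_rows_sum_to_one_and_chapman_kolmogorov(self, rng):
        for _ in range(20):
            r = random_rates(rng)
            t1, t2 = rng.uniform(0, 2, size=2)
            P1, P2 = transition_matrix(r, t1), transition_matrix(r, t2)
            assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
            assert np.abs(P1 @ P2
                          - transition_matrix(r, t1 + t2)).max() < 1e-10


class TestLoglik:
    def test_absorbing_two_tip_closed_form(self):
        # q01 = 0: state 1 cannot arise, all-1 data need a state-1 root
        t = read_newick("(A:0.6,B:1.1);")
        r = Mk2Rates(0.0, 0.9)
        ll = loglik(t, {"A": 1, "B": 1}, r)
        p11 = lambda bl: np.exp(-0.9 * bl)
        assert ll == pytest.approx(np.log(0.5 * p11(0.6) * p11(1.1)),
                                   abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_enumeration_on_six_tip_trees(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = read_newick(random_tree_newick(rng, 6))
        char = {lab: int(rng.random() > 0.5) for lab in tree.tip_labels}
        r = random_rates(rng)
        prior = "flat" if seed % 2 else "stationary"
        assert loglik(tree, char, r, root_prior=prior) == pytest.approx(
            enum_loglik(tree, char, r, root_prior=prior), abs=1e-9)

    def test_label_swap_symmetry(self, rng):
        tree = read_newick(random_tree_newick(rng, 7))
        char = {lab: int(rng.random() > 0.5) for lab in tree.tip_labels}
        r = Mk2Rates(0.4, 1.9)
        swapped = Mk2Rates(1.9, 0.4)
        flipped = {k: 1 - v for k, v in char.items()}
        assert loglik(tree, char, r) == pytest.approx(
            loglik(tree, flipped, swapped), abs=1e-10)

    def test_both_rates_zero_variable_char_is_minus_inf(self, quartet):
        ll = loglik(quartet, {"A": 1, "B": 1, "C": 0, "D": 0},
                    Mk2Rates(0.0, 0.0))
        assert ll == -np.inf

    def test_missing_tip_partial_one_one(self, quartet):
        # marginalising over a missing tip = summing both assignments
        r = Mk2Rates(0.7, 1.2)
        with_missing = loglik(quartet, {"A": 1, "B": 1, "C": 0, "D": None}, r)
        both = np.logaddexp(
            loglik(quartet, {"A": 1, "B": 1, "C": 0, "D": 0}, r),
            loglik(quartet, {"A": 1, "B": 1, "C": 0, "D": 1}, r))
        assert with_missing == pytest.approx(both, abs=1e-10)


class TestMarginalASR:
    @pytest.mark.parametrize("seed", range(6))
    def test_equals_restricted_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        tree = read_newick(random_tree_newick(rng, 6))
        char = {lab: int(rng.random() > 0.5) for lab in tree.tip_labels}
        r = random_rates(rng)
        rec = marginal_asr(tree, pd.Series(char), r)
        expect = enum_marginals(tree, char, r)
        for k, nid in enumerate(rec.node_ids):
            assert np.allclose(rec.proportional_likelihoods[k],
                               expect[nid], atol=1e-9)

    def test_pl_rows_sum_to_one(self, rng):
        tree = read_newick(random_tree_newick(rng, 10))
        char = {lab: int(rng.random() > 0.5) for lab in tree.tip_labels}
        rec = marginal_asr(tree, pd.Series(char), Mk2Rates(0.8, 0.3))
        assert np.allclose(rec.proportional_likelihoods.sum(axis=1), 1.0,
                           atol=1e-12)

    def test_clade_of_ones_has_pl1_majority_at_its_ancestor(self):
        tree = read_newick(
            "((A:0.1,B:0.1):3.0,((C:0.1,D:0.1):0.1,E:0.2):3.0);")
        char = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}
        rec = marginal_asr(tree, pd.Series(char), Mk2Rates(0.5, 0.2))
        frame = rec.to_frame()
        # ancestor of the all-1 clade (C,D,E)
        clade_pl1 = frame.loc["node2", "PL1"]
        assert clade_pl1 > 0.5

    def test_unequivocal_threshold(self, rng):
        tree = read_newick(random_tree_newick(rng, 8))
        char = {lab: int(rng.random() > 0.5) for lab in tree.tip_labels}
        rec1 = marginal_asr(tree, pd.Series(char), Mk2Rates(0.5, 0.9),
                            threshold=1.0)
        logr = np.abs(np.diff(np.log(rec1.proportional_likelihoods),
                              axis=1)).ravel()
        assert np.array_equal(rec1.unequivocal, logr >= 1.0)


class TestFitRates:
    def test_constant_character_is_degenerate_boundary(self, quartet):
        fit = fit_rates(quartet, pd.Series({"A": 1, "B": 1, "C": 1, "D": 1}))
        assert fit.degenerate
        assert fit.rates.q10 < 1e-2  # rate away from the observed state ~ 0

    def test_fitted_loglik_beats_grid(self):
        tree = simulate_tree(30, seed=3)
        sim = simulate_character(tree, Mk2Rates(1.0, 2.0), seed=4)
        fit = fit_rates(tree, sim.tip_states)
        for q01 in (0.1, 0.5, 1.0, 3.0):
            for q10 in (0.1, 0.5, 1.0, 3.0):
                assert fit.loglik >= loglik(
                    tree, sim.tip_states, Mk2Rates(q01, q10)) - 1e-6

    def test_shared_fit_recovers_rates_modestly(self):
        # small-scale recovery check; the full-scale one lives in the
        # acceptance suite
        tree = simulate_tree(100, seed=9)
        cols = {}
        for j in range(50):
            sim = simulate_character(
                tree, Mk2Rates(0.5, 1.5), root_prior="stationary",
                seed=np.random.default_rng(
                    np.random.SeedSequence(entropy=9, spawn_key=(j,))))
            cols[f"c{j}"] = sim.tip_states
        fit = fit_rates(tree, pd.DataFrame(cols), shared=True)
        assert fit.rates.q01 == pytest.approx(0.5, rel=0.5)
        assert fit.rates.q10 == pytest.approx(1.5, rel=0.5)

    def test_estimator_interface(self, quartet):
        model = Mk2Model().fit(
            quartet, pd.Series({"A": 1, "B": 1, "C": 0, "D": 0}))
        assert model.q01_ >= 0 and model.q10_ >= 0
        assert np.isfinite(model.loglik_)
        params = model.get_params()
        assert params["root_prior"] == "flat"
        rec = model.reconstruct(
            quartet, pd.Series({"A": 1, "B": 1, "C": 0, "D": 0}))
        assert rec.proportional_likelihoods.shape[1] == 2


class TestSimulation:
    def test_zero_rates_fix_root_state(self, quartet):
        sim = simulate_character(quartet, Mk2Rates(0.0, 0.0), root_state=1,
                                 seed=0)
        assert (sim.tip_states == 1).all()

    def test_zero_length_branches_copy_root(self):
        t = read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        sim = simulate_character(t, Mk2Rates(5.0, 5.0), root_state=0, seed=1)
        assert (sim.tip_states == 0).all()

    def test_reproducible_under_seed(self, quartet):
        a = simulate_character(quartet, Mk2Rates(1.0, 2.0), seed=42)
        b = simulate_character(quartet, Mk2Rates(1.0, 2.0), seed=42)
        assert a.tip_states.equals(b.tip_states)
        assert a.node_states.equals(b.node_states)

    def test_deep_tree_tip_frequency_near_stationary(self):
        # two tips far from the root: each tip ~ Bernoulli(pi1)
        t = read_newick("(A:50,B:50);")
        r = Mk2Rates(1.0, 3.0)  # pi1 = 0.25
        rng = np.random.default_rng(7)
        n = 10_000
        ones = 0
        for k in range(n):
            sim = simulate_character(t, r, root_prior="stationary", seed=rng)
            ones += sim.tip_states.iloc[0]
        freq = ones / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(freq - 0.25) < 3 * se
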