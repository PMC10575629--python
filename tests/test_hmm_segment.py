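import numpy as np
import pytest

from gscpipe import (
    HMMParams, StatePath, domains_from_statepath, fold_change_track,
    gen_chip_pair, init_semi_informed, make_bins, statepath_from_domains,
    statepath_loglik, viterbi_decode, viterbi_train,
)
from conftest import brute_force_viterbi, random_hmm_params


class TestParamsValidation:
    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="3 states"):
            HMMParams([0.5, 0.5], np.full((2, 2), 0.5), [0, 1], [1, 1])

    def test_unordered_means_rejected(self):
        u = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="strictly increasing"):
            HMMParams(u, np.tile(u, (3, 1)), [0.5, 0.0, -0.5], [1, 1, 1])

    def test_nonstochastic_rows_rejected(self):
        u = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="sum to 1"):
            HMMParams(u, np.full((3, 3), 0.5), [-1, 0, 1], [1, 1, 1])


class TestInitSemiInformed:
    def test_uniform_initial_and_transitions(self):
        params = init_semi_informed(np.random.default_rng(0).normal(size=100))
        np.testing.assert_allclose(params.initial_probs, 1 / 3)
        np.testing.assert_allclose(params.transition_matrix, 1 / 3)

    def test_standard_normal_quantile_means(self):
        """Percentile means of N(0,1) draws sit near (-1.28, 0, 1.28)."""
        values = np.random.default_rng(7).normal(size=1000)
        params = init_semi_informed(values)
        np.testing.assert_allclose(params.emission_means, [-1.2816, 0, 1.2816],
                                   atol=0.15)
        assert np.all(params.emission_sds == params.emission_sds[0])

    def test_degenerate_constant_signal_nudged_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            params = init_semi_informed(np.zeros(10))
        np.testing.assert_allclose(params.emission_means, [-1e-3, 0, 1e-3])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            init_semi_informed([0.0, 1.0])


class TestViterbiDecode:
    def test_single_bin_extreme_value(self, well_separated_params):
        path = viterbi_decode([5.0], well_separated_params)
        assert path.states.tolist() == [2]
        assert path.labels.tolist() == ["enriched"]

    def test_tie_breaks_toward_lowest_state(self):
        u = np.full(3, 1 / 3)
        params = HMMParams(u, np.tile(u, (3, 1)), [-1.0, 0.0, 1.0],
                           [0.5, 0.5, 0.5])
        # -0.5 is exactly between the depleted and nodiff means
        path = viterbi_decode([-0.5], params)
        assert path.states.tolist() == [0]

    def test_non_finite_value_rejected(self, well_separated_params):
        with pytest.raises(ValueError, match="index 1"):
            viterbi_decode([0.0, np.nan, 0.0], well_separated_params)

    def test_matches_brute_force_on_random_instances(self):
        """Decode equals exhaustive maximization over all 3**n paths."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(1, 8))
            params = random_hmm_params(rng)
            values = rng.normal(0, 1.5, size=n)
            path = viterbi_decode(values, params)
            oracle_path, oracle_score = brute_force_viterbi(values, params)
            assert path.log_likelihood == pytest.approx(oracle_score, abs=1e-8)
            assert path.states.tolist() == oracle_path.tolist()

    def test_chromosome_boundaries_restart_the_chain(self):
        """With two chromosomes, decoding equals brute force with a
        restart at the boundary, and permuting chromosome order only
        permutes the output."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            params = random_hmm_params(rng)
            v1 = rng.normal(size=3)
            v2 = rng.normal(size=3)
            joint = viterbi_decode(np.concatenate([v1, v2]), params,
                                   boundaries=[0, 3])
            o1, s1 = brute_force_viterbi(v1, params)
            o2, s2 = brute_force_viterbi(v2, params)
            assert joint.log_likelihood == pytest.approx(s1 + s2, abs=1e-8)
            assert joint.states.tolist() == o1.tolist() + o2.tolist()
            swapped = viterbi_decode(np.concatenate([v2, v1]), params,
                                     boundaries=[0, 3])
            assert swapped.states.tolist() == o2.tolist() + o1.tolist()


class TestStatepathLoglik:
    def test_single_bin_closed_form(self, well_separated_params):
        p = well_separated_params
        ll = statepath_loglik([0.5], p, np.array([2]))
        expected = np.log(1 / 3) + np.log(1 / (0.05 * np.sqrt(2 * np.pi)))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_viterbi_path_dominates_all_paths(self):
        """The decoded path maximizes the joint likelihood (checked by
        enumeration on small instances)."""
        import itertools
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            params = random_hmm_params(rng)
            values = rng.normal(size=n)
            best = viterbi_decode(values, params)
            for other in itertools.product(range(3), repeat=n):
                ll = statepath_loglik(values, params, np.array(other))
                assert ll <= best.log_likelihood + 1e-9

    def test_appending_a_bin_lowers_the_loglik(self):
        """With all log terms negative (unit emission SDs keep densities
        below 1), each extra bin lowers the path log-likelihood."""
        u = np.full(3, 1 / 3)
        params = HMMParams(u, np.tile(u, (3, 1)), [-0.5, 0.0, 0.5],
                           [1.0, 1.0, 1.0])
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1.0, size=12)
        lls = [viterbi_decode(values[:k], params).log_likelihood
               for k in range(1, 13)]
        assert np.all(np.diff(lls) < 0)

    def test_length_mismatch_rejected(self, well_separated_params):
        with pytest.raises(ValueError, match="length"):
            statepath_loglik([0.1, 0.2], well_separated_params, np.array([0]))


class TestViterbiTrain:
    def test_loglik_monotone_and_converges(self):
        rng = np.random.default_rng(10)
        u = np.full(3, 1 / 3)
        truth = HMMParams(u, np.array([[0.9, 0.05, 0.05],
                                       [0.05, 0.9, 0.05],
                                       [0.05, 0.05, 0.9]]),
                          [-0.5, 0.0, 0.5], [0.05] * 3)
        states = [0]
        for _ in range(1999):
            states.append(rng.choice(3, p=truth.transition_matrix[states[-1]]))
        values = rng.normal(truth.emission_means[states],
                            truth.emission_sds[states])
        params, path, log = viterbi_train(values)
        assert np.all(np.diff(log["log_likelihood"]) >= -1e-9)
        assert len(log) <= 1000
        np.testing.assert_allclose(params.emission_means, truth.emission_means,
                                   atol=0.02)
        assert (path.states == np.array(states)).mean() >= 0.95

    def test_recovery_from_generated_tracks(self, well_separated_params):
        """On synthetic tracks with well-separated truth, training
        recovers the emission means and >=95% of bin states."""
        chip, inp, truth = gen_chip_pair({"chr1": 5_000_000}, 500,
                                         well_separated_params, 500, seed=4)
        fc, mask = fold_change_track(chip, inp)
        params, path, _ = viterbi_train(fc.values,
                                        fc.bins.chromosome_boundaries())
        np.testing.assert_allclose(params.emission_means,
                                   well_separated_params.emission_means,
                                   atol=0.02)
        acc = (path.states == truth.true_statepath[mask]).mean()
        assert acc >= 0.95

    def test_fixed_point_returns_after_one_iteration(self, well_separated_params):
        rng = np.random.default_rng(1)
        values = rng.normal(0.5, 0.05, size=50)
        params, path, _ = viterbi_train(values)
        params2, path2, log2 = viterbi_train(values, init=params, max_iter=50)
        assert path2.states.tolist() == path.states.tolist()

    def test_invalid_controls_rejected(self, well_separated_params):
        with pytest.raises(ValueError, match="max_iter"):
            viterbi_train([0.0, 1.0, 2.0], max_iter=0)
        with pytest.raises(ValueError, match="tol"):
            viterbi_train([0.0, 1.0, 2.0], tol=0.0)


class TestDomains:
    def _bins(self, n, width=500):
        return make_bins({"chrA": width * n}, width)

    def test_runs_merge_into_domains(self):
        bins = self._bins(5)
        path = StatePath(np.array([2, 2, 1, 1, 0]), np.array([0]), 0.0)
        dom = domains_from_statepath(path, bins)
        rows = dom.intervals.to_records(index=False).tolist()
        assert rows == [("chrA", 0, 1000, "enriched"),
                        ("chrA", 1000, 2000, "nodiff"),
                        ("chrA", 2000, 2500, "depleted")]

    def test_discarded_bin_splits_a_domain(self):
        bins = self._bins(3).subset(np.array([True, False, True]))
        path = StatePath(np.array([2, 2]), np.array([0]), 0.0)
        dom = domains_from_statepath(path, bins)
        assert len(dom) == 2
        assert set(dom.intervals["state"]) == {"enriched"}

    def test_round_trip_relabels_bins(self):
        rng = np.random.default_rng(8)
        keep = rng.random(40) > 0.3
        bins = self._bins(40).subset(keep)
        states = rng.integers(0, 3, size=keep.sum())
        path = StatePath(states, np.array([0]), 0.0)
        dom = domains_from_statepath(path, bins)
        back = statepath_from_domains(dom, bins)
        assert back.tolist() == states.tolist()

    def test_inconsistent_lengths_rejected(self):
        path = StatePath(np.array([0, 1]), np.array([0]), 0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            domains_from_statepath(path, self._bins(3))
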