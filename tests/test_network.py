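import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from catpop import network as nw
from catpop import popcode as pc
from catpop._angles import TWO_PI, circ_dist, wrap_angle
from catpop.exceptions import (InvalidInputError, InvalidParameterError,
                               UndefinedPeakError)


class TestCategoryInput:
    def test_uniform_activity_gives_equal_drives(self, small_population, categories):
        act = pc.PopulationActivity(np.ones(small_population.n_units))
        drives = nw.category_input(act, small_population, categories)
        np.testing.assert_allclose(drives, drives[0], atol=1e-12)

    def test_tuning_at_center_drives_that_category(self, population, categories):
        for c, center in enumerate(categories.centers):
            act = pc.population_tuning(population, center)
            drives = nw.category_input(act, population, categories)
            assert np.argmax(drives) == c

    def test_single_active_unit_drives_nearest_category(self, small_population,
                                                        categories):
        # exhaustive over units: one-hot activity must recruit the category
        # whose center is circularly nearest the active unit's preferred hue
        for i, theta in enumerate(small_population.preferred_hues):
            act = np.zeros(small_population.n_units)
            act[i] = 1.0
            drives = nw.category_input(pc.PopulationActivity(act),
                                       small_population, categories)
            nearest = np.argmin(circ_dist(theta, categories.centers))
            if not np.isclose(circ_dist(theta, categories.centers).min(),
                              np.sort(circ_dist(theta, categories.centers))[1]):
                assert np.argmax(drives) == nearest

    def test_length_mismatch_rejected(self, small_population, categories):
        with pytest.raises(InvalidInputError):
            nw.category_input(pc.PopulationActivity(np.ones(5)),
                              small_population, categories)


class TestEstimateCategory:
    def test_argmax_and_tie_break(self):
        assert nw.estimate_category([1.0, 3.0, 2.0]) == 1
        assert nw.estimate_category([2.0, 2.0, 1.0]) == 0

    @settings(deadline=None, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_permutation_equivariance(self, perm):
        drives = np.array([0.5, 3.5, 2.0, -1.0])
        winner = nw.estimate_category(drives)
        permuted = drives[np.array(perm)]
        assert permuted[nw.estimate_category(permuted)] == drives[winner]

    def test_invalid_drives_rejected(self):
        with pytest.raises(InvalidInputError):
            nw.estimate_category([1.0])
        with pytest.raises(InvalidInputError):
            nw.estimate_category([1.0, np.nan])


class TestTopDownSignal:
    def test_zero_weight_gives_zero_vector(self, small_population, categories):
        params = nw.NetworkParams(lambda_cat=0.0)
        sig = nw.top_down_signal(1, small_population, categories, params)
        assert not sig.any()

    def test_peak_at_focal_hue(self, categories, default_params):
        pop = pc.make_uniform_population(12)
        sig = nw.top_down_signal(0, pop, categories, default_params)
        assert np.argmax(sig) == 0  # unit at the category-0 center (hue 0)
        assert sig.max() == pytest.approx(default_params.lambda_cat)

    def test_reflection_symmetry_about_center(self, categories, default_params):
        pop = pc.make_uniform_population(12)
        sig = nw.top_down_signal(0, pop, categories, default_params)
        np.testing.assert_allclose(sig[1:], sig[1:][::-1], rtol=1e-12)

    def test_invalid_index_rejected(self, small_population, categories,
                                    default_params):
        with pytest.raises(InvalidInputError):
            nw.top_down_signal(3, small_population, categories, default_params)


class TestUpdateStep:
    def test_pure_feedforward_passes_input_through(self, small_population,
                                                   categories, feedforward_params):
        state = nw.initial_state(small_population)
        b = pc.population_tuning(small_population, 1.0)
        new = nw.update_step(state, b, small_population, categories,
                             feedforward_params)
        np.testing.assert_array_equal(new.activity.rates, b.rates)
        assert new.step == 1

    def test_geometric_decay_without_input(self, small_population, categories):
        params = nw.NetworkParams(lambda_hue=0.6, lambda_cat=0.0)
        act = pc.population_tuning(small_population, 0.5)
        state = nw.NetworkState(activity=act, step=0)
        zero = pc.PopulationActivity(np.zeros(small_population.n_units))
        for k in range(1, 6):
            state = nw.update_step(state, zero, small_population, categories,
                                   params)
            np.testing.assert_allclose(state.activity.rates,
                                       0.6 ** k * act.rates, rtol=1e-12)

    def test_constant_input_converges_to_geometric_series_limit(
            self, small_population, categories, default_params):
        # closed-form oracle: fixed winner c, constant drive b
        # => a_inf = (b + topdown(c)) / (1 - lambda_hue)
        b = pc.population_tuning(small_population, categories.centers[1])
        state = nw.initial_state(small_population)
        for _ in range(200):
            state = nw.update_step(state, b, small_population, categories,
                                   default_params)
        td = nw.top_down_signal(1, small_population, categories, default_params)
        expected = (b.rates + td) / (1.0 - default_params.lambda_hue)
        np.testing.assert_allclose(state.activity.rates, expected, atol=1e-6)

    def test_boundedness_invariant(self, small_population, categories):
        params = nw.NetworkParams(lambda_hue=0.9, lambda_cat=0.4)
        bound = (small_population.gain + params.lambda_cat) / (1 - params.lambda_hue)
        rng = np.random.default_rng(0)
        state = nw.initial_state(small_population)
        for _ in range(100):
            b = pc.encode_stimulus(small_population, rng.uniform(0, TWO_PI),
                                   0.3, rng)
            state = nw.update_step(state, b, small_population, categories, params)
            assert state.activity.rates.max() <= bound + 1e-9


class TestDecoding:
    def test_peak_decoder_returns_nearest_grid_hue(self, small_population,
                                                   categories, feedforward_params):
        stim = 1.0
        traj = nw.run_trial([stim], small_population, categories,
                            feedforward_params)
        nearest = small_population.preferred_hues[
            np.argmin(circ_dist(stim, small_population.preferred_hues))]
        assert traj.decoded_peaks[0] == pytest.approx(nearest)

    def test_rotation_equivariance_of_peak(self, small_population):
        act = pc.population_tuning(small_population, 0.7).rates
        base = nw.decode_peak(pc.PopulationActivity(act), small_population)
        for k in (1, 3, 7):
            rolled = nw.decode_peak(pc.PopulationActivity(np.roll(act, k)),
                                    small_population)
            expected = wrap_angle(base + k * small_population.spacing)
            assert circ_dist(rolled, expected) < 1e-12

    def test_population_vector_exact_on_symmetric_profile(self, population):
        stim = population.preferred_hues[42]
        act = pc.population_tuning(population, stim)
        decoded = nw.population_vector_decode(act, population)
        assert circ_dist(decoded, stim) < 1e-10

    def test_population_vector_agrees_with_peak_within_grid(self, population,
                                                            rng):
        for _ in range(20):
            stim = rng.uniform(0, TWO_PI)
            act = pc.population_tuning(population, stim)
            pv = nw.population_vector_decode(act, population)
            pk = nw.decode_peak(act, population)
            assert circ_dist(pv, pk) <= population.spacing

    def test_all_zero_activity_flagged(self, small_population):
        zero = pc.PopulationActivity(np.zeros(small_population.n_units))
        with pytest.raises(UndefinedPeakError):
            nw.decode_peak(zero, small_population)


class TestRunTrial:
    def test_all_none_observations_stay_silent(self, small_population,
                                               categories, default_params):
        traj = nw.run_trial([None, None, None], small_population, categories,
                            default_params)
        assert not traj.activity_matrix().any()
        assert np.isnan(traj.decoded_peaks).all()

    def test_constant_stimulus_at_center_is_fixed_point(self, population,
                                                        categories,
                                                        default_params):
        center = categories.centers[2]
        traj = nw.run_trial([center] * 15, population, categories,
                            default_params)
        assert np.all(circ_dist(traj.decoded_peaks, center) < 1e-12)

    def test_empty_sequence_rejected(self, small_population, categories,
                                     default_params):
        with pytest.raises(InvalidParameterError):
            nw.run_trial([], small_population, categories, default_params)

    def test_batch_runner_matches_sequential_trials(self, small_population,
                                                    categories, default_params):
        stim = 2.2
        offsets = np.random.default_rng(3).normal(0, 0.15, size=(4, 6))
        batch = nw.run_trial_batch(stim, small_population, categories,
                                   default_params, n_steps=6, n_trials=4,
                                   noise_sd=0.15, noise_offsets=offsets)
        for trial in range(4):
            state = nw.initial_state(small_population)
            for t in range(6):
                b = pc.population_tuning(small_population,
                                         wrap_angle(stim + offsets[trial, t]))
                state = nw.update_step(state, b, small_population, categories,
                                       default_params)
            np.testing.assert_allclose(batch[trial], state.activity.rates,
                                       rtol=1e-12)

    def test_rotation_equivariance_of_trajectory(self, default_params):
        pop = pc.make_uniform_population(60)
        delta = 3 * pop.spacing
        cats_a = pc.CategorySet.equally_spaced(3)
        cats_b = pc.CategorySet.equally_spaced(3, offset=delta)
        obs = [0.3, 0.5, 0.4, 0.35, 0.3]
        ta = nw.run_trial(obs, pop, cats_a, default_params)
        tb = nw.run_trial([wrap_angle(o + delta) for o in obs], pop, cats_b,
                          default_params)
        np.testing.assert_allclose(
            wrap_angle(ta.decoded_peaks + delta), tb.decoded_peaks, atol=1e-9)


class TestExactOnlinePosterior:
    def make_config(self, kappa_cat=4.0, switch=0.1, noise=0.3):
        cats = pc.CategorySet(centers=np.array([0.5, np.pi + 0.5]),
                              kappa_cat=kappa_cat)
        return pc.GenerativeConfig(categories=cats, switch_prob=switch,
                                   obs_noise_sd=noise, horizon=3)

    def test_posteriors_normalized(self, categories, rng):
        cfg = pc.GenerativeConfig(categories=categories, horizon=12)
        _, _, obs = pc.generate_stimulus_sequence(cfg, rng)
        _, hue_post, cat_post = nw.exact_online_posterior(obs, cfg, 72)
        np.testing.assert_allclose(hue_post.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(cat_post.sum(axis=1), 1.0, atol=1e-12)

    def test_single_step_is_plain_bayes_rule(self):
        cfg = self.make_config()
        grid, hue_post, _ = nw.exact_online_posterior([1.0], cfg, 48)
        # direct elementwise product: mixture prior x wrapped-normal likelihood
        prior = np.zeros(48)
        for c in range(2):
            e = np.exp(cfg.categories.kappa_cat
                       * np.cos(grid - cfg.categories.centers[c]))
            prior += 0.5 * e / e.sum()
        lik = np.zeros(48)
        for k in range(-3, 4):
            lik += norm.pdf(1.0 - grid + TWO_PI * k, scale=cfg.obs_noise_sd)
        expected = prior * lik
        expected /= expected.sum()
        np.testing.assert_allclose(hue_post[0], expected, rtol=1e-8)

    def test_matches_brute_force_path_enumeration(self):
        # independent oracle: sum over all category paths explicitly
        import itertools
        import warnings
        cfg = self.make_config()
        obs = [0.8, 0.9, 3.8]
        G = 12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            grid, hue_post, cat_post = nw.exact_online_posterior(obs, cfg, G)

        emis = np.exp(cfg.categories.kappa_cat
                      * np.cos(grid[None, :] - cfg.categories.centers[:, None]))
        emis /= emis.sum(axis=1, keepdims=True)
        lik = np.zeros((len(obs), G))
        for t, x in enumerate(obs):
            for k in range(-3, 4):
                lik[t] += norm.pdf(x - grid + TWO_PI * k, scale=cfg.obs_noise_sd)
        T = cfg.transition_matrix()

        for t in range(3):
            post = np.zeros((2, G))
            for path in itertools.product(range(2), repeat=t + 1):
                w = 0.5
                for a, b in zip(path[:-1], path[1:]):
                    w *= T[a, b]
                for k in range(t):  # marginalize earlier hues
                    w *= float(emis[path[k]] @ lik[k])
                post[path[t]] += w * emis[path[t]] * lik[t]
            post /= post.sum()
            np.testing.assert_allclose(hue_post[t], post.sum(axis=0), rtol=1e-9)
            np.testing.assert_allclose(cat_post[t], post.sum(axis=1), rtol=1e-9)


class TestOracleAgreement:
    def test_network_tracks_exact_filter_in_stable_category_regime(self):
        # slow-switching limit: no category transitions within the horizon
        pop = pc.make_uniform_population(60)
        cats = pc.CategorySet.equally_spaced(3)
        cfg = pc.GenerativeConfig(categories=cats, switch_prob=0.0, horizon=20)
        params = nw.NetworkParams()
        means = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            _, _, obs = pc.generate_stimulus_sequence(cfg, r)
            cors = nw.oracle_profile_correlation(obs, pop, cats, params, cfg)
            means.append(cors.mean())
        assert np.mean(means) >= 0.9

    def test_category_tracking_accuracy(self):
        # winner-take-all matches the true category after a settling period
        pop = pc.make_uniform_population(60)
        cats = pc.CategorySet.equally_spaced(3)
        cfg = pc.GenerativeConfig(categories=cats, switch_prob=0.0, horizon=12)
        params = nw.NetworkParams()
        hits = total = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            cseq, _, obs = pc.generate_stimulus_sequence(cfg, r)
            traj = nw.run_trial(list(obs), pop, cats, params)
            est = traj.category_estimates()[3:]
            hits += sum(e == cseq[0] for e in est)
            total += len(est)
        assert hits / total >= 0.95
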