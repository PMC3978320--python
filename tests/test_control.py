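"""Control-network dynamics: trial integration, conflict, adaptation."""

import numpy as np
import pytest

from decicomp.control import (
    ControlParameters,
    NetworkState,
    TaskDemand,
    adapt_task_weights,
    comparator_solo_latency,
    conflict,
    resting_comparison_activation,
    run_trial,
    step_dynamics,
)
from decicomp.place_coding import DIGIT_TUNING, LENGTH_TUNING, encode_value
from decicomp.stimuli import DecimalFraction, StimulusPair


def _pair(a, b, ptype="a.bc"):
    return StimulusPair(a=DecimalFraction.parse(a), b=DecimalFraction.parse(b), ptype=ptype)


NOISELESS = ControlParameters(noise_sd=0.0)


class TestStepDynamics:
    def test_noise_off_trajectory_is_deterministic(self, fitted):
        pair = _pair("2.04", "2.91", "a.0c")
        r1, _ = run_trial(pair, fitted.bank, TaskDemand(), NOISELESS, np.random.default_rng(1))
        r2, _ = run_trial(pair, fitted.bank, TaskDemand(), NOISELESS, np.random.default_rng(999))
        assert (r1.steps, r1.response, r1.correct) == (r2.steps, r2.response, r2.correct)

    def test_full_persistence_freezes_activations(self, fitted):
        params = ControlParameters(tau=1.0, noise_sd=0.0)
        ff = fitted.bank.trial_inputs(_pair("2.04", "2.91", "a.0c"))
        state = NetworkState()
        state.comparison[:] = 0.25
        out = step_dynamics(state, ff, TaskDemand(), params)
        np.testing.assert_array_equal(out.comparison, state.comparison)
        np.testing.assert_array_equal(out.response, state.response)

    def test_stepping_past_the_cap_is_rejected(self, fitted):
        ff = fitted.bank.trial_inputs(_pair("2.04", "2.91", "a.0c"))
        state = NetworkState(step=200)
        with pytest.raises(ValueError, match="cap"):
            step_dynamics(state, ff, TaskDemand(), NOISELESS)

    def test_larger_second_member_drives_its_response_node(self, fitted):
        """2.04 vs 2.91, noise off: the 'second member larger' node wins."""
        result, _ = run_trial(_pair("2.04", "2.91", "a.0c"), fitted.bank, TaskDemand(), NOISELESS)
        assert result.response == "b"
        assert result.correct


class TestConflict:
    @pytest.mark.parametrize("rl, rr, expected", [(0.0, 0.9, 0.0), (0.0, 0.0, 0.0)])
    def test_silent_side_means_no_conflict(self, rl, rr, expected):
        state = NetworkState(response=np.array([rl, rr]))
        assert conflict(state, NOISELESS) == expected

    def test_conflict_increases_with_coactivation(self):
        low = NetworkState(response=np.array([0.5, 0.5]))
        high = NetworkState(response=np.array([0.8, 0.8]))
        assert conflict(high, NOISELESS) > conflict(low, NOISELESS) > 0

    def test_energy_form(self):
        state = NetworkState(response=np.array([0.6, 0.7]))
        p = ControlParameters()
        assert conflict(state, p) == pytest.approx(p.beta_con * abs(p.w_inh_resp) * 0.6 * 0.7)


class TestAdaptation:
    def test_zero_conflict_converges_to_baseline(self):
        demand = TaskDemand()
        demand.task_activation = demand.baseline * 2.0
        state = NetworkState(conflict=0.0)
        for _ in range(60):
            demand = adapt_task_weights(demand, state, NOISELESS)
        np.testing.assert_allclose(demand.task_activation, demand.baseline, atol=1e-8)

    def test_conflict_strengthens_active_couplings(self):
        demand = TaskDemand()
        state = NetworkState(conflict=0.5)
        state.comparison[:] = 0.6
        adapted = adapt_task_weights(demand, state, NOISELESS)
        assert np.all(adapted.task_activation >= demand.baseline)
        assert adapted.task_activation[1] > demand.baseline[1]

    def test_couplings_stay_in_bounds(self):
        p = ControlParameters(task_weight_max=2.0)
        demand = TaskDemand()
        state = NetworkState(conflict=1e3)
        state.comparison[:] = 1.0
        for _ in range(50):
            demand = adapt_task_weights(demand, state, p)
        assert np.all(demand.task_activation <= 2.0)
        assert np.all(demand.task_activation >= 0.0)

    def test_incongruent_trial_boosts_coupling_more_than_congruent(self, fitted):
        """One high-conflict (incongruent) trial strengthens the tenth
        coupling more than one congruent trial from the same start."""
        demand = TaskDemand()
        _, st_inc = run_trial(
            _pair("7.14", "7.6", "a.b"), fitted.bank, demand, ControlParameters(),
            np.random.default_rng(3),
        )
        _, st_con = run_trial(
            _pair("2.7", "2.91", "a.b"), fitted.bank, demand, ControlParameters(),
            np.random.default_rng(3),
        )
        assert st_inc.conflict > st_con.conflict
        after_inc = adapt_task_weights(demand, st_inc, ControlParameters())
        after_con = adapt_task_weights(demand, st_con, ControlParameters())
        assert after_inc.task_activation[1] > after_con.task_activation[1]


class TestRunTrial:
    def test_untrained_weights_are_rejected(self):
        from decicomp.comparator import TrainingConfig, train_delta
        from decicomp.control import ComparatorBank

        rng = np.random.default_rng(0)
        digit = train_delta(TrainingConfig(n_trials=0), DIGIT_TUNING, rng)
        length = train_delta(TrainingConfig(n_trials=0, frequency_weights=np.ones(4)),
                             LENGTH_TUNING, rng)
        bank = ComparatorBank(digit=digit, length=length)
        with pytest.raises(ValueError, match="not fully trained"):
            run_trial(_pair("2.04", "2.91", "a.0c"), bank, TaskDemand(), NOISELESS)

    def test_unreachable_threshold_caps_as_error(self, fitted):
        """With full persistence nothing ever moves, the threshold is
        never reached, and the trial is a capped error."""
        params = ControlParameters(tau=1.0, noise_sd=0.0)
        result, _ = run_trial(_pair("2.04", "2.91", "a.0c"), fitted.bank, TaskDemand(), params)
        assert result.steps == params.max_steps
        assert result.response == "none"
        assert not result.correct

    def test_comparison_layer_threshold_reading_is_available(self, fitted):
        params = ControlParameters(noise_sd=0.0, threshold_layer="comparison")
        result, _ = run_trial(_pair("2.04", "2.91", "a.0c"), fitted.bank, TaskDemand(), params)
        assert result.response in ("a", "b", "none")

    def test_unknown_threshold_layer_rejected(self):
        with pytest.raises(ValueError, match="threshold_layer"):
            ControlParameters(threshold_layer="input")

    def test_resting_state_is_a_fixed_point_below_half(self):
        p = ControlParameters()
        rest = resting_comparison_activation(p)
        assert 0.0 < rest < 0.5


class TestComparatorSpeed:
    def test_length_comparison_is_fastest_at_matched_distance(self, fitted):
        """Per-comparison overtraining makes the number-of-digits
        comparison faster than a digit comparison of the same numerical
        distance (distance 1: every digit pair is slower or undecided)."""
        len_lat = comparator_solo_latency(
            fitted.length, encode_value(3, LENGTH_TUNING), encode_value(2, LENGTH_TUNING)
        )
        digit_lats = [
            comparator_solo_latency(
                fitted.digit, encode_value(d + 1, DIGIT_TUNING), encode_value(d, DIGIT_TUNING)
            )
            for d in range(9)
        ]
        assert np.isfinite(len_lat)
        assert len_lat < np.mean(digit_lats)

    def test_length_not_slower_than_tenth_over_stimulus_set(self, fitted, stimuli_440):
        """Over the a.b items the solo length latency never exceeds the
        solo tenth-digit latency (they tie at step resolution because
        tenth distances are 3-5 by design while length distance is 1)."""
        lat_len, lat_tenth = [], []
        for p in stimuli_440:
            if p.ptype != "a.b":
                continue
            lat_len.append(
                comparator_solo_latency(
                    fitted.length,
                    encode_value(p.a.n_digits, LENGTH_TUNING),
                    encode_value(p.b.n_digits, LENGTH_TUNING),
                )
            )
            lat_tenth.append(
                comparator_solo_latency(
                    fitted.digit,
                    encode_value(p.a.tenth, DIGIT_TUNING),
                    encode_value(p.b.tenth, DIGIT_TUNING),
                )
            )
        assert np.mean(lat_len) <= np.mean(lat_tenth)
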