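"""Model facade: build, fit (train), and simulate in the statsmodels style.

``DecimalComparisonModel`` collects the architecture's configuration
(control dynamics, task demand, training schedules).  ``fit`` trains the
shared digit comparator and the number-of-digits comparator with the
delta rule and returns a ``ComparisonModelFit`` results object carrying
the trained weights and training diagnostics; simulation of trials and
experiments hangs off the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .comparator import (
    ComparatorWeights,
    TrainingConfig,
    digit_training_config,
    length_training_config,
    train_delta,
)
from .control import ComparatorBank, ControlParameters, TaskDemand, run_trial
from .experiment import N_PARTICIPANTS, SimulationRun, run_experiment
from .place_coding import DIGIT_TUNING, LENGTH_TUNING
from .stimuli import StimulusPair

__all__ = ["DecimalComparisonModel", "ComparisonModelFit", "TrainingFailure"]


class TrainingFailure(RuntimeError):
    """A comparator failed to reach perfect pair accuracy after training."""

    def __init__(self, name: str, accuracy: float, n_trials: int):
        self.accuracy = accuracy
        super().__init__(
            f"{name} comparator reached only {accuracy:.1%} accuracy on its "
            f"ordered value pairs after {n_trials} training trials"
        )


@dataclass
class DecimalComparisonModel:
    """The decimal-fraction comparison architecture, ready to be trained."""

    control: ControlParameters = field(default_factory=ControlParameters)
    demand: TaskDemand = field(default_factory=TaskDemand)
    digit_training: TrainingConfig = field(default_factory=digit_training_config)
    length_training: TrainingConfig = field(default_factory=length_training_config)

    @classmethod
    def from_config(cls, config) -> "DecimalComparisonModel":
        """Build the model from a ``ModelConfig`` (see :mod:`decicomp.config`)."""
        return cls(
            control=config.control_parameters(),
            demand=config.task_demand(),
            digit_training=config.digit_training_config(),
            length_training=config.length_training_config(),
        )

    def fit(self, seed: int = 0, require_perfect: bool = True) -> "ComparisonModelFit":
        """Train both comparators with the delta rule.

        One digit network is trained and its weights shared by the unit,
        tenth and hundredth comparators; the 4-node length network is
        trained independently.  Raises :class:`TrainingFailure` when a
        network does not decide all its ordered unequal value pairs
        correctly (disable with ``require_perfect=False``).
        """
        digit_ss, length_ss = np.random.SeedSequence(seed).spawn(2)
        digit = train_delta(self.digit_training, DIGIT_TUNING, np.random.default_rng(digit_ss))
        length = train_delta(self.length_training, LENGTH_TUNING, np.random.default_rng(length_ss))
        if require_perfect:
            if digit.accuracy != 1.0:
                raise TrainingFailure("digit", digit.accuracy, self.digit_training.n_trials)
            if length.accuracy != 1.0:
                raise TrainingFailure("length", length.accuracy, self.length_training.n_trials)
        return ComparisonModelFit(model=self, digit=digit, length=length, seed=seed)


@dataclass
class ComparisonModelFit:
    """Results of fitting: trained weights plus simulation entry points."""

    model: DecimalComparisonModel
    digit: ComparatorWeights
    length: ComparatorWeights
    seed: int

    @property
    def bank(self) -> ComparatorBank:
        return ComparatorBank(digit=self.digit, length=self.length)

    def run_trial(self, pair: StimulusPair, seed: int | None = None, demand: TaskDemand | None = None):
        """Simulate a single trial (noisy if the control parameters say so)."""
        rng = np.random.default_rng(seed) if seed is not None else None
        result, _state = run_trial(
            pair, self.bank, demand or self.model.demand, self.model.control, rng
        )
        return result

    def simulate(
        self,
        pairs: list[StimulusPair],
        n_participants: int = N_PARTICIPANTS,
        seed: int = 0,
    ) -> SimulationRun:
        """Simulate the full experiment over ``pairs``."""
        return run_experiment(
            self.bank,
            pairs,
            demand=self.model.demand,
            params=self.model.control,
            n_participants=n_participants,
            seed=seed,
        )

    def summary(self) -> str:
        """Plain-text account of the fitted comparators."""
        m = self.model
        lines = [
            "Decimal-fraction comparison model — training summary",
            "====================================================",
            f"training seed:           {self.seed}",
            f"digit network:           {self.digit.spec.n_nodes}-node banks, "
            f"{m.digit_training.n_trials} delta-rule trials "
            f"(lr {m.digit_training.learning_rate})",
            f"  frequency weights:     {np.round(m.digit_training.frequency_weights, 3).tolist()}",
            f"  pair accuracy:         {self.digit.accuracy:.1%} of 90 ordered pairs",
            f"length network:          {self.length.spec.n_nodes}-node banks, "
            f"{m.length_training.n_trials} delta-rule trials "
            f"(lr {m.length_training.learning_rate})",
            f"  pair accuracy:         {self.length.accuracy:.1%} of 12 ordered pairs",
            f"control: tau={m.control.tau}, beta_in={m.control.beta_in}, "
            f"theta={m.control.theta}, noise_sd={m.control.noise_sd}, "
            f"cap={m.control.max_steps}",
            f"task activations:        {np.round(self.model.demand.task_activation, 3).tolist()} "
            "(unit, tenth, hundredth, length)",
            f"response weights:        {np.round(self.model.demand.response_weight, 3).tolist()}",
        ]
        return "\n".join(lines)
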