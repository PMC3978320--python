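"""The simulated comparison experiment.

A run presents the full stimulus set once to each of ``n_participants``
simulated participants.  Each participant gets an independent trial
order and an independent noise stream, both derived from one master
seed, so any single participant can be re-simulated in isolation.  The
task-demand couplings adapt trial by trial within a participant and
reset between participants.  Capped trials (threshold never reached)
count as errors, and — as in the analysis the run feeds — error trials
are excluded from RT summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .control import ComparatorBank, ControlParameters, TaskDemand, adapt_task_weights, run_trial
from .stimuli import StimulusPair

__all__ = ["SimulationRun", "run_experiment", "exclude_errors"]

N_PARTICIPANTS = 22

TRIAL_COLUMNS = [
    "participant",
    "trial",
    "item_id",
    "type",
    "relation",
    "steps",
    "response",
    "correct",
    "conflict",
]


@dataclass
class SimulationRun:
    """Trial-level outcome table of one simulated experiment."""

    trials: pd.DataFrame
    n_participants: int
    master_seed: int

    @property
    def loss_fraction(self) -> float:
        return 1.0 - float(self.trials["correct"].mean())

    def summarize(self):
        from .analysis import summarize_run

        return summarize_run(self)


def simulate_participant(
    participant: int,
    pairs: list[StimulusPair],
    bank: ComparatorBank,
    demand: TaskDemand,
    params: ControlParameters,
    rng: np.random.Generator,
) -> list[dict]:
    """One participant: shuffled order, trial-by-trial control adaptation."""
    order = rng.permutation(len(pairs))
    state_demand = demand.copy()
    rows = []
    for t, idx in enumerate(order):
        pair = pairs[idx]
        result, state = run_trial(pair, bank, state_demand, params, rng)
        state_demand = adapt_task_weights(state_demand, state, params)
        rows.append(
            {
                "participant": participant,
                "trial": t,
                "item_id": pair.item_id,
                "type": pair.ptype,
                "relation": pair.relation,
                "steps": result.steps,
                "response": result.response,
                "correct": result.correct,
                "conflict": result.conflict_trace,
            }
        )
    return rows


def run_experiment(
    bank: ComparatorBank,
    pairs: list[StimulusPair],
    demand: TaskDemand | None = None,
    params: ControlParameters | None = None,
    n_participants: int = N_PARTICIPANTS,
    seed: int = 0,
) -> SimulationRun:
    """Simulate ``n_participants`` sessions over the full item set."""
    bank.require_trained()
    demand = demand or TaskDemand()
    params = params or ControlParameters()
    children = np.random.SeedSequence(seed).spawn(n_participants)
    rows: list[dict] = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        rows.extend(simulate_participant(p, pairs, bank, demand, params, rng))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SimulationRun(trials=trials, n_participants=n_participants, master_seed=seed)


def exclude_errors(run: SimulationRun) -> tuple[pd.DataFrame, float]:
    """Correct-only trial table plus the fraction of trials lost.

    Wrong responses and capped (no-response) trials are removed; no
    further RT trimming is applied to simulated step counts.
    """
    correct = run.trials[run.trials["correct"]].copy()
    loss = 1.0 - len(correct) / len(run.trials)
    return correct, loss
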