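"""Conflict-monitoring control network wrapped around the four comparators.

The trial dynamics integrate four evidence sources — unit digits, tenth
digits, hundredth digits and number of digits — under task-demand
modulation.  Each comparison node is a leaky sigmoid unit driven by its
comparator's raw feedforward input scaled by ``C + task_activation`` of
its attribute and inhibited by the opposing node; two response nodes
("first member larger" vs "second member larger") pool the comparison
activations of their side through the fixed attribute response weights
and compete via lateral inhibition.  Gaussian noise is injected into
every sigmoid argument at every step.  The simulated response time is
the number of steps until a response node reaches the threshold theta;
trials that never reach it within the step cap count as errors.

A conflict-monitoring unit tracks the energy-style co-activation of the
two response nodes (exponentially smoothed over steps).  After every
trial the conflict level drives a Hebbian update of the couplings
between the task-demand nodes and their comparison networks, so control
adapts locally, trial by trial.

The published parameter set leaves the exact transfer functions of the
control layers open; the response layer here applies a gain and a bias
to its sigmoid argument (``response_gain``, ``response_bias``), the
minimal extension under which the printed response threshold of 0.8 is
reachable at all with the printed response weights.  Their defaults are
calibrated once so that the model operates in the reported regime of
roughly ten processing steps per decision (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit as sigmoid

from .comparator import W_INH_COMP, ComparatorWeights, feedforward_input
from .place_coding import DIGIT_TUNING, LENGTH_TUNING, PlaceCode, encode_value
from .stimuli import DecimalFraction, StimulusPair

__all__ = [
    "ATTRIBUTES",
    "ControlParameters",
    "TaskDemand",
    "NetworkState",
    "TrialResult",
    "ComparatorBank",
    "step_dynamics",
    "conflict",
    "adapt_task_weights",
    "run_trial",
    "comparator_solo_latency",
]

#: Order of the four attribute networks throughout the package.
ATTRIBUTES = ("unit", "tenth", "hundredth", "length")


@dataclass(frozen=True)
class ControlParameters:
    """All dynamics constants of the control network.

    The first block holds the published values; ``response_gain`` and
    ``response_bias`` are the calibrated transfer constants of the
    response layer and ``threshold_layer`` selects where the decision
    threshold is read out (the response layer by default; the
    comparison layer is the alternative literal reading).
    """

    tau: float = 0.8  # activation persistence per step
    beta_in: float = 0.2  # input gain
    w_inh_resp: float = -0.5  # response-layer lateral inhibition
    C: float = 0.7  # baseline input scaling
    beta_con: float = 1.0  # conflict gain
    lambda_con: float = 0.8  # conflict smoothing rate across steps
    lambda_w: float = 0.7  # task-weight persistence across trials
    alpha_w: float = 1.0  # Hebbian learning gain
    beta_w: float = 0.5  # weighting of the conflict-Hebbian increment
    theta: float = 0.8  # response threshold
    max_steps: int = 200  # cap on simulated response time
    noise_sd: float = 0.11  # SD of the per-node, per-step Gaussian noise
    response_gain: float = 20.0  # calibrated response-layer sigmoid gain
    response_bias: float = 0.5  # calibrated response-layer sigmoid bias
    comparison_bias: float = -0.8  # calibrated comparison-layer sigmoid bias
    threshold_layer: str = "response"  # or "comparison"
    task_weight_max: float = 5.0  # upper clip of adapted task couplings

    def __post_init__(self) -> None:
        if self.threshold_layer not in ("response", "comparison"):
            raise ValueError(f"threshold_layer must be 'response' or 'comparison', got {self.threshold_layer!r}")


def _as_attr_array(values: dict[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(values, dict):
        return np.array([float(values[a]) for a in ATTRIBUTES])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (4,):
        raise ValueError("expected one value per attribute (unit, tenth, hundredth, length)")
    return arr.copy()


@dataclass
class TaskDemand:
    """Per-attribute task-node activations and comparison-to-response weights.

    Defaults mirror the attentional weighting derived from where readers
    actually look: units are ignored (activation 0), tenths carry almost
    all weight (1.5), hundredths nearly none (0.01) and the number of
    digits an intermediate amount (1.0).  ``task_activation`` is the
    adaptable coupling; ``baseline`` is its resting value, the fixed
    point of the Hebbian adaptation at zero conflict.
    """

    task_activation: np.ndarray = field(
        default_factory=lambda: _as_attr_array({"unit": 0.0, "tenth": 1.5, "hundredth": 0.01, "length": 1.0})
    )
    response_weight: np.ndarray = field(
        default_factory=lambda: _as_attr_array({"unit": 0.1, "tenth": 1.0, "hundredth": 0.1, "length": 0.7})
    )
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.task_activation = _as_attr_array(self.task_activation)
        self.response_weight = _as_attr_array(self.response_weight)
        if self.baseline is None:
            self.baseline = self.task_activation.copy()
        else:
            self.baseline = _as_attr_array(self.baseline)

    def copy(self) -> "TaskDemand":
        return TaskDemand(
            task_activation=self.task_activation.copy(),
            response_weight=self.response_weight.copy(),
            baseline=self.baseline.copy(),
        )


@dataclass
class NetworkState:
    """Dynamic state of one trial: comparison (4 x {L, R}), response, conflict."""

    comparison: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))
    response: np.ndarray = field(default_factory=lambda: np.zeros(2))
    conflict: float = 0.0
    step: int = 0


def resting_comparison_activation(params: "ControlParameters") -> float:
    """No-input fixed point of a comparison node pair.

    Between trials the comparison layers idle at the symmetric fixed
    point of ``a = sigmoid(beta_in * w_inh_comp * a + comparison_bias)``;
    trials start from this resting level (the response nodes start
    silent — the overt response has just been released).
    """
    a = 0.5
    for _ in range(100):
        new = float(sigmoid(params.beta_in * W_INH_COMP * a + params.comparison_bias))
        if abs(new - a) < 1e-12:
            return new
        a = new
    return a


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated comparison trial.

    ``steps`` is the simulated response time in processing steps;
    ``response`` is "a" (first/top member judged larger), "b", or
    "none" when the threshold was never reached (an error).
    """

    steps: int
    response: str
    correct: bool
    conflict_trace: float


class ComparatorBank:
    """The four trained comparators plus input encoding for a stimulus pair.

    The single trained digit network serves units, tenths and hundredths
    alike (its weights are shared); the 4-node network compares the
    number of digits.  A member without a hundredth digit contributes a
    zero input vector to the hundredth comparator's corresponding bank —
    the string-length information lives in the length network instead.
    """

    def __init__(self, digit: ComparatorWeights, length: ComparatorWeights):
        if digit.spec.n_nodes != DIGIT_TUNING.n_nodes:
            raise ValueError("digit comparator must use 10-node banks")
        if length.spec.n_nodes != LENGTH_TUNING.n_nodes:
            raise ValueError("length comparator must use 4-node banks")
        self.digit = digit
        self.length = length

    def require_trained(self) -> None:
        for name, w in (("digit", self.digit), ("length", self.length)):
            if not w.accuracy == 1.0:
                raise ValueError(
                    f"{name} comparator is not fully trained "
                    f"(accuracy {w.accuracy}); refusing to simulate trials"
                )

    @staticmethod
    def _digit_code(d: int | None) -> PlaceCode:
        if d is None:
            return PlaceCode(activations=np.zeros(DIGIT_TUNING.n_nodes), encoded_value=-1)
        return encode_value(d, DIGIT_TUNING)

    def trial_inputs(self, pair: StimulusPair) -> np.ndarray:
        """Raw feedforward inputs of all comparison nodes, shape (4, 2).

        Row order follows ``ATTRIBUTES``; columns are the (first-member
        larger, second-member larger) comparison nodes.
        """
        a, b = pair.a, pair.b
        ff = np.empty((4, 2))
        ff[0] = feedforward_input(self.digit, self._digit_code(a.unit), self._digit_code(b.unit))
        ff[1] = feedforward_input(self.digit, self._digit_code(a.tenth), self._digit_code(b.tenth))
        ff[2] = feedforward_input(
            self.digit, self._digit_code(a.hundredth), self._digit_code(b.hundredth)
        )
        ff[3] = feedforward_input(
            self.length,
            encode_value(a.n_digits, LENGTH_TUNING),
            encode_value(b.n_digits, LENGTH_TUNING),
        )
        return ff


def step_dynamics(
    state: NetworkState,
    ff: np.ndarray,
    demand: TaskDemand,
    params: ControlParameters,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the network by one time step.

    Comparison nodes leaky-integrate the sigmoid of their task-scaled
    feedforward drive plus lateral inhibition; response nodes pool the
    same-side comparison activations through the attribute response
    weights.  Noise (SD ``noise_sd``) enters every sigmoid argument.
    """
    if state.step >= params.max_steps:
        raise ValueError(f"trial already at the {params.max_steps}-step cap")
    p = params
    if p.noise_sd > 0 and rng is not None:
        eps_comp = rng.normal(0.0, p.noise_sd, size=(4, 2))
        eps_resp = rng.normal(0.0, p.noise_sd, size=2)
    else:
        eps_comp = 0.0
        eps_resp = 0.0

    gain = (p.C + demand.task_activation)[:, None]
    comp_arg = (
        p.beta_in * (gain * ff + W_INH_COMP * state.comparison[:, ::-1])
        + p.comparison_bias
        + eps_comp
    )
    comparison = p.tau * state.comparison + (1 - p.tau) * sigmoid(comp_arg)

    pool = demand.response_weight @ comparison  # (2,) same-side pooled evidence
    resp_net = p.beta_in * (pool + p.w_inh_resp * state.response[::-1]) + eps_resp
    resp_arg = p.response_gain * resp_net + p.response_bias
    response = p.tau * state.response + (1 - p.tau) * sigmoid(resp_arg)

    new = NetworkState(
        comparison=comparison,
        response=response,
        conflict=state.conflict,
        step=state.step + 1,
    )
    new.conflict = p.lambda_con * state.conflict + (1 - p.lambda_con) * conflict(new, p)
    return new


def conflict(state: NetworkState, params: ControlParameters) -> float:
    """Instantaneous response conflict: energy of the response co-activation.

    ``beta_con * |w_inh_resp| * a_L * a_R`` — zero when either response
    node is silent and strictly increasing in their product.
    """
    r = np.clip(state.response, 0.0, 1.0)
    return float(params.beta_con * abs(params.w_inh_resp) * r[0] * r[1])


def adapt_task_weights(
    demand: TaskDemand, state: NetworkState, params: ControlParameters
) -> TaskDemand:
    """End-of-trial Hebbian adaptation of the task-demand couplings.

    Each coupling relaxes toward its baseline plus a conflict-gated
    Hebbian increment (pre = demand-node activity of the comparison
    task, fixed at 1; post = mean end-of-trial activation of that
    attribute's comparison nodes):

        T_k <- lambda_w T_k
               + (1 - lambda_w) (baseline_k + beta_w alpha_w conflict post_k)

    clipped to [0, task_weight_max].  With zero conflict the couplings
    decay geometrically back to their baselines; high-conflict trials
    transiently strengthen the couplings that were active.
    """
    post = state.comparison.mean(axis=1)
    boost = params.beta_w * params.alpha_w * state.conflict * 1.0 * post
    new_T = params.lambda_w * demand.task_activation + (1 - params.lambda_w) * (
        demand.baseline + boost
    )
    new = demand.copy()
    new.task_activation = np.clip(new_T, 0.0, params.task_weight_max)
    return new


def run_trial(
    pair: StimulusPair,
    bank: ComparatorBank,
    demand: TaskDemand,
    params: ControlParameters,
    rng: np.random.Generator | None = None,
) -> tuple[TrialResult, NetworkState]:
    """Simulate one trial from a zero-activation state to the decision.

    Returns the trial outcome and the final network state (whose
    smoothed conflict feeds the trial-by-trial adaptation).  The
    decision is the side of the first node of ``threshold_layer`` to
    reach theta; simultaneous crossings are resolved by the higher
    activation, exact ties uniformly at random.
    """
    bank.require_trained()
    ff = bank.trial_inputs(pair)
    state = NetworkState()
    state.comparison[:] = resting_comparison_activation(params)
    p = params
    crossed_side: int | None = None
    while state.step < p.max_steps:
        state = step_dynamics(state, ff, demand, p, rng)
        if p.threshold_layer == "response":
            levels = state.response
        else:
            levels = state.comparison.max(axis=0)
        over = levels >= p.theta
        if over.any():
            if over.all():
                if levels[0] == levels[1]:
                    crossed_side = int(rng.integers(2)) if rng is not None else 0
                else:
                    crossed_side = int(np.argmax(levels))
            else:
                crossed_side = int(np.argmax(over))
            break
    if crossed_side is None:
        result = TrialResult(
            steps=p.max_steps, response="none", correct=False, conflict_trace=state.conflict
        )
    else:
        response = "a" if crossed_side == 0 else "b"
        larger = "a" if pair.a.value > pair.b.value else "b"
        result = TrialResult(
            steps=state.step,
            response=response,
            correct=response == larger,
            conflict_trace=state.conflict,
        )
    return result, state


def comparator_solo_latency(
    weights: ComparatorWeights,
    left: PlaceCode,
    right: PlaceCode,
    params: ControlParameters | None = None,
) -> float:
    """Steps for a bare comparator's winning node to reach theta.

    The comparator runs outside the control network (no task
    modulation, no noise): its single-pass evidence sigmoid(W x) is
    leaky-integrated with the network's persistence tau.  Returns
    ``inf`` when the evidence asymptote never clears the threshold.
    This operationalises how quickly one attribute alone could drive a
    decision — the heavily trained number-of-digits comparison resolves
    faster than the digit-magnitude comparisons.
    """
    p = params or ControlParameters()
    e = sigmoid(feedforward_input(weights, left, right))
    a = np.zeros(2)
    for step in range(1, p.max_steps + 1):
        a = p.tau * a + (1 - p.tau) * e
        if a.max() >= p.theta:
            return float(step)
    return float("inf")
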