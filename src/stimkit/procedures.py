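"""Trial sequencing and adaptive procedures.

Covers the method of constant stimuli (fixed value, all values in random
order per repetition block, random draws with replacement) and transformed
up-down staircases (1-up/1-down, 1-up/2-down, 1-up/3-down, ...), plus a
simulated psychometric observer and a maximum-likelihood psychometric fit
used to close the loop in headless runs.

A transformed n-up/m-down rule decreases the stimulus value after m
consecutive correct responses and increases it after n consecutive errors;
the 1-up/2-down variant converges on the stimulus level yielding
sqrt(1/2) ~ 70.7% correct, and 1-up/1-down on the 50% point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, ndtr

from .model import NumericList, Section, ValidationError

__all__ = [
    "TrialPlan",
    "StaircaseConfig",
    "StaircaseState",
    "PsychometricObserver",
    "PsychometricFit",
    "expand_section_trials",
    "staircase_next",
    "staircase_estimate",
    "simulate_response",
    "fit_psychometric",
]


@dataclass
class TrialPlan:
    """One trial's variable assignments, keyed by target path."""

    trial_index: int
    assignments: dict[str, float]
    section: str


# ---------------------------------------------------------------------------
# Method of constant stimuli
# ---------------------------------------------------------------------------

def expand_section_trials(
    section: Section,
    lists: dict[str, NumericList] | Sequence[NumericList],
    rng: np.random.Generator,
) -> list[TrialPlan]:
    """Expand a section's variable bindings into a full trial plan.

    Selection methods:

    - ``fixed``: every trial uses the list's first value.
    - ``all_values_random_order``: each repetition is an independent random
      permutation of the full list, so ``n_values * repetitions`` trials in
      total with every value appearing exactly ``repetitions`` times.
    - ``random_with_replacement``: an independent uniform draw per trial.

    Adaptive bindings are sequenced lazily trial-by-trial by the runner
    (see :func:`staircase_next`); passing one here raises.
    """
    if not isinstance(lists, dict):
        lists = {l.name: l for l in lists}

    for vb in section.variables:
        if vb.selection_method == "adaptive":
            if vb.adaptive_config is None:
                raise ValidationError(
                    f"adaptive binding {vb.target!r} has no adaptive_config"
                )
            raise ValueError(
                "adaptive bindings are sequenced lazily by the runner, "
                "not expanded to a fixed plan"
            )

    block_lens = set()
    for vb in section.variables:
        if vb.selection_method == "all_values_random_order":
            block_lens.add(len(lists[vb.list].values))
    if len(block_lens) > 1:
        raise ValidationError(
            "all_values_random_order bindings in one section must use lists "
            f"of equal length, got lengths {sorted(block_lens)}"
        )
    block_len = block_lens.pop() if block_lens else 1

    n_trials = section.repetitions * block_len
    columns: dict[str, list[float]] = {}
    for vb in section.variables:
        values = lists[vb.list].values
        if vb.selection_method == "fixed":
            columns[vb.target] = [values[0]] * n_trials
        elif vb.selection_method == "random_with_replacement":
            idx = rng.integers(0, len(values), n_trials)
            columns[vb.target] = [values[i] for i in idx]
        elif vb.selection_method == "all_values_random_order":
            seq: list[float] = []
            for _ in range(section.repetitions):
                seq.extend(values[i] for i in rng.permutation(len(values)))
            columns[vb.target] = seq
        else:
            raise ValidationError(
                f"unknown selection_method {vb.selection_method!r}"
            )

    return [
        TrialPlan(
            trial_index=i,
            assignments={t: col[i] for t, col in columns.items()},
            section=section.name,
        )
        for i in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# Transformed up-down staircases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    """Transformed n-up/m-down rule with fixed additive steps."""

    n_up: int = 1
    n_down: int = 2
    step_up: float = 1.0
    step_down: float = 1.0
    start_value: float = 0.0
    n_reversals_stop: int = 8
    min_value: float = -np.inf
    max_value: float = np.inf

    def __post_init__(self) -> None:
        if self.step_up <= 0 or self.step_down <= 0:
            raise ValueError("staircase steps must be > 0")
        if self.n_up < 1 or self.n_down < 1:
            raise ValueError("up/down run lengths must be >= 1")
        if self.n_reversals_stop < 2:
            raise ValueError("n_reversals_stop must be >= 2")
        if self.min_value >= self.max_value:
            raise ValueError("min_value must be below max_value")

    @classmethod
    def from_dict(cls, d: dict) -> "StaircaseConfig":
        rule = d.get("rule")
        kw = dict(d)
        if rule is not None:
            kw.pop("rule")
            kw["n_up"], kw["n_down"] = int(rule[0]), int(rule[1])
        for b, sub in (("min_value", -np.inf), ("max_value", np.inf)):
            if kw.get(b) is None:
                kw[b] = sub
        return cls(**kw)


@dataclass
class StaircaseState:
    """Mutable-by-replacement staircase state; step with :func:`staircase_next`."""

    current_value: float
    run_correct: int = 0
    run_incorrect: int = 0
    reversals: list[float] = field(default_factory=list)
    history: list[tuple[float, bool]] = field(default_factory=list)
    last_direction: int = 0  # +1 up, -1 down, 0 none yet
    finished: bool = False

    @classmethod
    def start(cls, config: StaircaseConfig) -> "StaircaseState":
        v = min(max(config.start_value, config.min_value), config.max_value)
        return cls(current_value=v)


def staircase_next(
    state: StaircaseState, config: StaircaseConfig, correct: bool
) -> StaircaseState:
    """Advance the staircase by one trial's response.

    After ``n_down`` consecutive correct responses the value decreases by
    ``step_down``; after ``n_up`` consecutive errors it increases by
    ``step_up``.  A change of stepping direction records the turning-point
    value as a reversal; the staircase finishes once ``n_reversals_stop``
    reversals are recorded.  Values are clamped to [min_value, max_value].
    """
    if state.finished:
        raise RuntimeError("cannot step a finished staircase")
    history = state.history + [(state.current_value, bool(correct))]
    value = state.current_value
    run_c, run_i = state.run_correct, state.run_incorrect
    reversals = list(state.reversals)
    last_dir = state.last_direction

    step_dir = 0
    if correct:
        run_c, run_i = run_c + 1, 0
        if run_c >= config.n_down:
            step_dir = -1
            run_c = 0
    else:
        run_i, run_c = run_i + 1, 0
        if run_i >= config.n_up:
            step_dir = +1
            run_i = 0

    if step_dir != 0:
        if last_dir != 0 and step_dir != last_dir:
            reversals.append(value)
        last_dir = step_dir
        step = config.step_down if step_dir < 0 else config.step_up
        value = min(max(value + step_dir * step, config.min_value),
                    config.max_value)

    return StaircaseState(
        current_value=value,
        run_correct=run_c,
        run_incorrect=run_i,
        reversals=reversals,
        history=history,
        last_direction=last_dir,
        finished=len(reversals) >= config.n_reversals_stop,
    )


def staircase_estimate(state: StaircaseState, n_last_reversals: int) -> float:
    """Threshold estimate: arithmetic mean of the last n reversal values."""
    if n_last_reversals < 1:
        raise ValueError("n_last_reversals must be >= 1")
    if len(state.reversals) < n_last_reversals:
        raise ValueError(
            f"only {len(state.reversals)} reversals recorded, "
            f"need {n_last_reversals}"
        )
    return float(np.mean(state.reversals[-n_last_reversals:]))


# ---------------------------------------------------------------------------
# Simulated observer and psychometric fitting
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray | float, threshold: float, slope: float,
             form: str) -> np.ndarray | float:
    if form == "logistic":
        return expit(slope * (np.asarray(x, dtype=float) - threshold))
    if form == "cumulative_gaussian":
        return ndtr(slope * (np.asarray(x, dtype=float) - threshold))
    raise ValueError(f"unknown psychometric form {form!r}")


@dataclass
class PsychometricObserver:
    """Stochastic observer answering via a psychometric function.

    P(correct | value) = guess + (1 - guess - lapse) * F(|value|), where F is
    a logistic or cumulative-Gaussian sigmoid with F(threshold) = 0.5.  With
    guess 0.5 this is the standard two-alternative forced-choice observer.
    """

    threshold: float
    slope: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.02
    form: str = "logistic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess_rate <= 1.0):
            raise ValueError("guess_rate must lie in [0, 1]")
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must lie in [0, 1)")

    def prob_correct(self, value: float) -> float:
        f = _sigmoid(abs(value), self.threshold, self.slope, self.form)
        return float(
            self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * f
        )

    def simulate_correct(self, value: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.prob_correct(value))

    @classmethod
    def from_dict(cls, d: dict) -> "PsychometricObserver":
        return cls(
            threshold=float(d["threshold"]),
            slope=float(d["slope"]),
            guess_rate=float(d.get("guess_rate", 0.5)),
            lapse_rate=float(d.get("lapse_rate", 0.02)),
            form=str(d.get("form", "logistic")),
        )


def simulate_response(
    observer: PsychometricObserver,
    stimulus_value: float,
    correct_side: Any,
    rng: np.random.Generator,
) -> Any:
    """Emit the correct side with probability P(correct | value), else the
    other side.  Sides may be +1/-1 or the strings "left"/"right"."""
    correct = observer.simulate_correct(stimulus_value, rng)
    if correct:
        return correct_side
    if correct_side in ("left", "right"):
        return "right" if correct_side == "left" else "left"
    return -correct_side


@dataclass(frozen=True)
class PsychometricFit:
    threshold: float
    slope: float
    log_likelihood: float


def fit_psychometric(
    trials: Sequence[tuple[float, bool]],
    form: str = "logistic",
    fixed_guess: float = 0.5,
    fixed_lapse: float = 0.02,
) -> PsychometricFit:
    """Maximum-likelihood psychometric fit under a binomial model.

    ``trials`` holds (stimulus value, correct) pairs; values enter through
    their magnitude, matching a discrimination task with symmetric levels.
    Guess and lapse rates are fixed; threshold and slope are estimated from
    a fixed deterministic start, so refits of identical data are identical.
    Data with only one outcome overall cannot constrain the threshold: a
    boundary warning is issued and the threshold is reported as the midpoint
    between the extreme values.
    """
    x = np.abs([t[0] for t in trials]).astype(float)
    k = np.array([bool(t[1]) for t in trials], dtype=float)
    if len(x) == 0:
        raise ValueError("no trials to fit")
    levels, inv = np.unique(x, return_inverse=True)
    n_per = np.bincount(inv)
    k_per = np.bincount(inv, weights=k)

    lo, hi = float(levels.min()), float(levels.max())
    if k_per.sum() == 0 or k_per.sum() == len(x) or len(levels) < 2:
        warnings.warn(
            "psychometric data at the response boundary (single outcome or "
            "single level); threshold reported as midpoint of the tested range",
            stacklevel=2,
        )
        mid = (lo + hi) / 2.0
        span = max(hi - lo, 1e-12)
        return PsychometricFit(threshold=mid, slope=4.0 / span,
                               log_likelihood=0.0)

    span = max(hi - lo, 1e-12)

    def nll(params: np.ndarray) -> float:
        threshold, log_slope = params
        f = _sigmoid(levels, threshold, np.exp(log_slope), form)
        p = fixed_guess + (1.0 - fixed_guess - fixed_lapse) * f
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -float(
            np.sum(k_per * np.log(p) + (n_per - k_per) * np.log(1.0 - p))
        )

    x0 = np.array([float(np.median(levels)), np.log(4.0 / span)])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    threshold, log_slope = res.x
    return PsychometricFit(
        threshold=float(threshold),
        slope=float(np.exp(log_slope)),
        log_likelihood=float(-res.fun),
    )
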