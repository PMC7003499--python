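"""Agent-based simulator of the two-cup guessing experiments.

Each simulated child plays a short session: optional training trials with
explicit feedback ("yes that's right" / "hmm that's not right"), then a
single test trial in which the experimenter — who either looked inside the
cups (knowledgeable) or explicitly did not (ignorant) — responds to the
child's first guess only with the neutral query "is that your final
guess?".  The child updates her belief with the feedback model and converts
the posterior into a switch/stay decision through a :class:`SwitchRule`.

Randomness is counter-based: every child owns an independent stream derived
from the top-level seed and the child's (condition, index) coordinates, so
enlarging a cohort never reshuffles earlier children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exact_stats import Counts2x2
from .exceptions import (
    DataError,
    DegenerateSplitError,
    EmptySummaryError,
    ParameterError,
)
from .feedback_model import (
    BeliefState,
    FeedbackParams,
    Knowledge,
    RuleKind,
    Statement,
    SwitchRule,
    posterior_belief,
    switch_probability,
)

__all__ = [
    "ExperimentDesign",
    "TrialRecord",
    "FitResult",
    "paper_designs",
    "simulate_cohort",
    "summarize_switching",
    "median_split_by_age",
    "fit_switch_model",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
]

_SIDES = ("left", "right")

#: Bounds for the neutral-query likelihood ratio in the fit.
LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one behavioral experiment.

    ``training_feedback`` lists the statements delivered after the first
    guess of each training trial, e.g. two confirmations, or one
    confirmation and one correction in randomized order
    (``randomize_training_order``).  Ages are drawn uniformly over
    ``age_range_months``.
    """

    name: str
    training_feedback: tuple[Statement, ...] = ()
    conditions: tuple[Knowledge, ...] = (Knowledge.KNOWLEDGEABLE, Knowledge.IGNORANT)
    n_per_condition: int = 22
    age_range_months: tuple[int, int] = (48, 80)
    randomize_training_order: bool = False

    def __post_init__(self) -> None:
        if self.n_per_condition <= 0:
            raise ParameterError(
                f"n_per_condition must be positive, got {self.n_per_condition}"
            )
        lo, hi = self.age_range_months
        if lo > hi or lo <= 0:
            raise ParameterError(f"invalid age range {self.age_range_months}")
        if not all(isinstance(s, Statement) for s in self.training_feedback):
            raise ParameterError("training_feedback must contain Statement values")

    @property
    def n_training_trials(self) -> int:
        return len(self.training_feedback)


def paper_designs() -> dict[str, ExperimentDesign]:
    """The four study layouts: sample sizes, training feedback, age ranges.

    * exp1/exp2 — two confirmation trials, then the test trial (n = 22 and
      18 per condition; ages 51-70 and 48-72 months).
    * exp3 — one confirmation and one correction in randomized order
      (n = 36 per condition, sticker and causal task collapsed; 48-80 mo).
    * exp4 — no training at all: the test trial is the whole session
      (n = 36 per condition; 48-71 months).
    """
    C, I = Statement.CORRECT, Statement.INCORRECT
    return {
        "exp1": ExperimentDesign("exp1", (C, C), n_per_condition=22, age_range_months=(51, 70)),
        "exp2": ExperimentDesign("exp2", (C, C), n_per_condition=18, age_range_months=(48, 72)),
        "exp3": ExperimentDesign(
            "exp3", (C, I), n_per_condition=36, age_range_months=(48, 80),
            randomize_training_order=True,
        ),
        "exp4": ExperimentDesign("exp4", (), n_per_condition=36, age_range_months=(48, 71)),
    }


@dataclass(frozen=True)
class TrialRecord:
    """One child x trial outcome."""

    child_id: str
    experiment: str
    condition: Knowledge
    age_months: int
    trial_kind: str  # "training" | "test"
    initial_choice: str  # "left" | "right"
    final_choice: str
    switched: bool

    def __post_init__(self) -> None:
        if self.trial_kind not in ("training", "test"):
            raise ParameterError(f"bad trial_kind {self.trial_kind!r}")
        if self.initial_choice not in _SIDES or self.final_choice not in _SIDES:
            raise ParameterError("choices must be 'left' or 'right'")
        if self.switched != (self.initial_choice != self.final_choice):
            raise ParameterError("switched flag inconsistent with choices")
        if self.age_months <= 0:
            raise ParameterError("age_months must be positive")


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _age_adjust(p: float, age: int, mid_age: float, slope: float) -> float:
    """Shift a switch probability on the log-odds scale by slope * (age - mid)."""
    if slope == 0.0 or p <= 0.0 or p >= 1.0:
        return p
    return _sigmoid(math.log(p / (1.0 - p)) + slope * (age - mid_age))


def _child_records(
    design: ExperimentDesign,
    condition: Knowledge,
    cond_idx: int,
    child_idx: int,
    params: FeedbackParams,
    rule: SwitchRule,
    seed: int,
    prior: BeliefState,
    age_slope: float,
) -> list[TrialRecord]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cond_idx, child_idx)))
    lo, hi = design.age_range_months
    age = int(rng.integers(lo, hi + 1))
    mid_age = (lo + hi) / 2.0
    child_id = f"{design.name}-{condition.value}-{child_idx:04d}"
    records: list[TrialRecord] = []

    feedback = list(design.training_feedback)
    if design.randomize_training_order and feedback:
        rng.shuffle(feedback)

    def play(statement_knowledge: Knowledge, statement: Statement, kind: str) -> None:
        initial = _SIDES[int(rng.integers(2))]
        belief = posterior_belief(prior, statement, statement_knowledge, params)
        p_switch = switch_probability(belief, rule)
        if kind == "test":
            p_switch = _age_adjust(p_switch, age, mid_age, age_slope)
        switched = bool(rng.random() < p_switch)
        final = _SIDES[1 - _SIDES.index(initial)] if switched else initial
        records.append(
            TrialRecord(
                child_id=child_id,
                experiment=design.name,
                condition=condition,
                age_months=age,
                trial_kind=kind,
                initial_choice=initial,
                final_choice=final,
                switched=switched,
            )
        )

    # Training: the experimenter looked, so feedback comes from the
    # knowledgeable statement model ("correct" -> stay, "incorrect" ->
    # switch, up to lapse, given the default beta_c = alpha_i = 0).
    for statement in feedback:
        play(Knowledge.KNOWLEDGEABLE, statement, "training")
    # Test trial: the only feedback is the neutral query, interpreted
    # through the condition's knowledge state.
    play(condition, Statement.NEUTRAL, "test")
    return records


def simulate_cohort(
    design: ExperimentDesign,
    params: FeedbackParams,
    rule: SwitchRule,
    seed: int,
    prior: BeliefState | None = None,
    age_slope: float = 0.0,
) -> list[TrialRecord]:
    """Simulate one cohort through the given design.

    Parameters
    ----------
    seed
        Top-level seed; identical inputs give bit-identical output.
    prior
        Learner's prior that her initial guess is correct (default 0.5).
    age_slope
        Optional log-odds change in test-trial switch probability per month
        of age (0 disables the age link).  The studies report only a
        directional age effect, so the synthetic link is a configurable
        logistic tilt around the mid-age of the design's range.
    """
    prior = BeliefState() if prior is None else prior
    out: list[TrialRecord] = []
    for cond_idx, condition in enumerate(design.conditions):
        for child_idx in range(design.n_per_condition):
            out.extend(
                _child_records(
                    design, condition, cond_idx, child_idx,
                    params, rule, seed, prior, age_slope,
                )
            )
    return out


def summarize_switching(records: list[TrialRecord]) -> dict[str, Counts2x2]:
    """Per-experiment 2x2 tables of test-trial switching.

    Row 1 is the knowledgeable condition (switched, stayed), row 2 the
    ignorant condition.  Order of the input records is irrelevant.
    """
    tests = [r for r in records if r.trial_kind == "test"]
    if not tests:
        raise EmptySummaryError("no test trials to summarize")
    out: dict[str, Counts2x2] = {}
    for exp in sorted({r.experiment for r in tests}):
        rows = []
        for cond in (Knowledge.KNOWLEDGEABLE, Knowledge.IGNORANT):
            sub = [r for r in tests if r.experiment == exp and r.condition is cond]
            switched = sum(r.switched for r in sub)
            rows.append((switched, len(sub) - switched))
        out[exp] = Counts2x2.from_rows(*rows)
    return out


def median_split_by_age(records: list[TrialRecord]) -> Counts2x2:
    """Split test trials at the median age and cross with switch/stay.

    Row 1 is the older half, row 2 the younger; children exactly at the
    median go to the younger group (deterministic tie-break, immaterial for
    continuous synthetic ages).
    """
    tests = [r for r in records if r.trial_kind == "test"]
    if not tests:
        raise EmptySummaryError("no test trials to split")
    ages = np.array([r.age_months for r in tests])
    if len(np.unique(ages)) < 2:
        raise DegenerateSplitError("need at least 2 distinct ages for a median split")
    med = float(np.median(ages))
    older = [r for r in tests if r.age_months > med]
    younger = [r for r in tests if r.age_months <= med]
    return Counts2x2.from_rows(
        (sum(r.switched for r in older), len(older) - sum(r.switched for r in older)),
        (sum(r.switched for r in younger), len(younger) - sum(r.switched for r in younger)),
    )


@dataclass(frozen=True)
class FitResult:
    """Inversion of the feedback model against observed switch counts.

    Only the neutral-query likelihood ratio
    ``lambda = P(neutral | correct) / P(neutral | incorrect)`` is
    identifiable from switch/stay counts — ``alpha_c`` and ``beta_i`` enter
    the test-trial likelihood through this ratio alone.  Under probability
    matching from an indifferent prior, the ignorant arm's switch
    probability is 0.5 for every lapse, so the lapse cannot be estimated
    from these counts either; it is taken from the rule the caller
    conditions on.  ``lambda_ci`` is the 95% profile-likelihood interval.
    """

    lambda_hat: float
    lapse_hat: float
    loglik: float
    identifiable: bool
    lambda_ci: tuple[float, float]


def _p_switch_k(lam: float, lapse: float) -> float:
    """Knowledgeable-arm switch probability under probability matching:
    posterior odds from an even prior are lambda, so the raw switch
    probability is 1 / (1 + lambda), then lapse-mixed."""
    return (1.0 - lapse) / (1.0 + lam) + lapse / 2.0


def fit_switch_model(counts: Counts2x2, rule: SwitchRule) -> FitResult:
    """Maximum-likelihood fit of the neutral-query likelihood ratio.

    ``counts`` holds (switched, stayed) for the knowledgeable condition in
    row 1 and the ignorant condition in row 2.  The binomial likelihood of
    both arms is maximized over ``lambda`` with the lapse fixed at
    ``rule.lapse``; the ignorant arm's probability is pinned at 0.5 by the
    model and contributes a constant.  With no knowledgeable observations
    the ratio is unidentified and ``identifiable`` is False.
    """
    if rule.kind is not RuleKind.PROBABILITY_MATCHING:
        raise ParameterError(
            "fit_switch_model inverts the probability-matching link; "
            f"got rule kind {rule.kind.value!r}"
        )
    if counts.total == 0:  # unreachable via Counts2x2, kept for clarity
        raise DataError("all-zero table")
    k_k, n_k = counts.a, counts.a + counts.b
    k_i, n_i = counts.c, counts.c + counts.d
    lapse = rule.lapse
    lo, hi = LAMBDA_BOUNDS

    ll_ignorant = float(_sps.binom.logpmf(k_i, n_i, 0.5)) if n_i > 0 else 0.0

    if n_k == 0:
        return FitResult(
            lambda_hat=math.nan,
            lapse_hat=lapse,
            loglik=ll_ignorant,
            identifiable=False,
            lambda_ci=(math.nan, math.nan),
        )

    def loglik(lam: float) -> float:
        return float(_sps.binom.logpmf(k_k, n_k, _p_switch_k(lam, lapse))) + ll_ignorant

    # Closed-form MLE: the binomial likelihood is maximized where the model
    # probability equals the empirical proportion, clipped to the reachable
    # range (lapse/2, 1 - lapse/2) and the lambda bounds.
    p_hat = k_k / n_k
    raw = (p_hat - lapse / 2.0) / (1.0 - lapse) if lapse < 1.0 else 0.5
    if raw >= 1.0:
        lam_hat = lo
    elif raw <= 0.0:
        lam_hat = hi
    else:
        lam_hat = min(max(1.0 / raw - 1.0, lo), hi)

    ll_max = loglik(lam_hat)
    crit = ll_max - _sps.chi2.ppf(0.95, df=1) / 2.0

    def _bisect(a: float, b: float) -> float:
        # loglik crosses crit once between a (inside) and b (outside), in log-lambda
        fa, fb = loglik(a) - crit, loglik(b) - crit
        if fb > 0:
            return b
        la, lb = math.log(a), math.log(b)
        for _ in range(200):
            lm = 0.5 * (la + lb)
            if loglik(math.exp(lm)) - crit > 0:
                la = lm
            else:
                lb = lm
        return math.exp(0.5 * (la + lb))

    ci = (_bisect(lam_hat, lo), _bisect(lam_hat, hi))
    return FitResult(
        lambda_hat=lam_hat,
        lapse_hat=lapse,
        loglik=ll_max,
        identifiable=True,
        lambda_ci=ci,
    )


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = [
    "child_id", "experiment", "condition", "age_months",
    "trial_kind", "initial_choice", "final_choice", "switched",
]


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "child_id": r.child_id,
                "experiment": r.experiment,
                "condition": r.condition.value,
                "age_months": r.age_months,
                "trial_kind": r.trial_kind,
                "initial_choice": r.initial_choice,
                "final_choice": r.final_choice,
                "switched": r.switched,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            child_id=str(row.child_id),
            experiment=str(row.experiment),
            condition=Knowledge(row.condition),
            age_months=int(row.age_months),
            trial_kind=str(row.trial_kind),
            initial_choice=str(row.initial_choice),
            final_choice=str(row.final_choice),
            switched=bool(row.switched),
        )
        for row in frame.itertuples()
    ]


def write_records_csv(records: list[TrialRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[TrialRecord]:
    return frame_to_records(pd.read_csv(path))
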