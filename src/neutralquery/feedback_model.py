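"""Generative model of informant feedback and the learner's belief update.

The setting: a learner (a preschool-aged child in the motivating experiments)
makes a two-alternative guess (e.g. which of two cups hides a sticker) and an
informant replies with one of three statements — "correct", "incorrect", or a
*neutral query* such as "is that your final guess?".  The learner's problem is
to decide what the neutral query means.

Two causal structures are distinguished:

* **Knowledgeable informant** — the informant knows the true state of the
  world, so her statement depends on whether the learner's guess was correct.
  The conditional statement distribution is parameterized by
  :class:`FeedbackParams`:

  =========  ==========  ============  ====================
  guess      "correct"   "incorrect"   neutral query
  =========  ==========  ============  ====================
  correct    ``alpha_c`` ``beta_c``    ``1 - alpha_c - beta_c``
  incorrect  ``alpha_i`` ``beta_i``    ``1 - alpha_i - beta_i``
  =========  ==========  ============  ====================

* **Ignorant informant** — the informant does not know the answer, so the
  statement is conditionally independent of the world state and carries no
  evidence about the guess.

With the natural restrictions ``beta_c ~ 0`` (an informant rarely calls a
correct guess wrong) and ``alpha_i ~ 0``, the neutral query's evidential
import is governed entirely by the *feedback bias*: if ``alpha_c > beta_i``
(a "positivity bias" — praise for correct answers is more forthcoming than
censure for incorrect ones), a neutral query from a knowledgeable informant
is more probable after an incorrect guess and should *lower* the learner's
belief that her guess was right, rationally producing answer switching.

Belief updating is Bayes rule in odds form.  We fix the odds convention as
``correct : incorrect`` of the learner's *initial guess*, so a likelihood
ratio below 1 is evidence the guess was wrong (and favors switching).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .exceptions import ImpossibleEvidenceError, ParameterError

__all__ = [
    "Knowledge",
    "Statement",
    "Regime",
    "FeedbackParams",
    "BeliefState",
    "SwitchRule",
    "DEFAULT_IGNORANT_MARGINAL",
    "EMPIRICAL_PARAMS",
    "statement_likelihood",
    "posterior_odds",
    "posterior_belief",
    "classify_regime",
    "switch_probability",
    "predicted_switch_probability",
]

_PROB_TOL = 1e-12  # slack for floating-point probability sums


class Knowledge(enum.Enum):
    """Epistemic state of the informant."""

    KNOWLEDGEABLE = "knowledgeable"
    IGNORANT = "ignorant"


class Statement(enum.Enum):
    """The informant's follow-up to the learner's initial guess.

    ``NEUTRAL`` covers "is that your final guess?", "are you sure?", or
    repeating the question — one category: a follow-up that carries no
    explicit correct/incorrect feedback.
    """

    CORRECT = "correct"
    INCORRECT = "incorrect"
    NEUTRAL = "neutral"


class Regime(enum.Enum):
    """Feedback-bias regime of a knowledgeable informant."""

    UNBIASED = "unbiased"
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class FeedbackParams:
    """Conditional statement probabilities of a knowledgeable informant.

    Parameters
    ----------
    alpha_c
        P("correct" | learner's guess is correct).
    beta_i
        P("incorrect" | learner's guess is incorrect).
    beta_c
        P("incorrect" | guess correct).  Defaults to 0: informants
        essentially never tell a correct guesser she is wrong.
    alpha_i
        P("correct" | guess incorrect).  Defaults to 0 for the symmetric
        reason.  Both remain settable for robustness analyses.

    The neutral-query cell in each row is the remainder, so each row of the
    statement table sums to 1 by construction.
    """

    alpha_c: float
    beta_i: float
    beta_c: float = 0.0
    alpha_i: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_c", "beta_i", "beta_c", "alpha_i"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be a probability in [0, 1], got {v!r}")
        if self.alpha_c + self.beta_c > 1.0 + _PROB_TOL:
            raise ParameterError(
                f"alpha_c + beta_c = {self.alpha_c + self.beta_c} exceeds 1; "
                "the neutral cell would be negative"
            )
        if self.alpha_i + self.beta_i > 1.0 + _PROB_TOL:
            raise ParameterError(
                f"alpha_i + beta_i = {self.alpha_i + self.beta_i} exceeds 1; "
                "the neutral cell would be negative"
            )

    @property
    def neutral_given_correct(self) -> float:
        return max(0.0, 1.0 - self.alpha_c - self.beta_c)

    @property
    def neutral_given_incorrect(self) -> float:
        return max(0.0, 1.0 - self.alpha_i - self.beta_i)

    @property
    def likelihood_ratio_neutral(self) -> float:
        """P(neutral | correct) / P(neutral | incorrect) for a knowledgeable
        informant — the single number that determines what a neutral query
        does to the learner's odds.  ``inf`` when the denominator is 0."""
        denom = self.neutral_given_incorrect
        num = self.neutral_given_correct
        if denom == 0.0:
            return math.inf if num > 0.0 else math.nan
        return num / denom

    def to_dict(self) -> dict:
        return {
            "alpha_c": self.alpha_c,
            "beta_c": self.beta_c,
            "alpha_i": self.alpha_i,
            "beta_i": self.beta_i,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeedbackParams":
        return cls(
            alpha_c=float(d["alpha_c"]),
            beta_i=float(d["beta_i"]),
            beta_c=float(d.get("beta_c", 0.0)),
            alpha_i=float(d.get("alpha_i", 0.0)),
        )


#: Feedback parameters estimated from coded parent-child exchanges:
#: 59/64 correct answers drew praise, 13/20 incorrect answers drew censure.
EMPIRICAL_PARAMS = FeedbackParams(alpha_c=59 / 64, beta_i=13 / 20)

#: Statement marginal for an ignorant informant.  An informant who does not
#: know the answer cannot truthfully assert "correct"/"incorrect", so the
#: default puts all mass on the neutral query.  Any marginal is accepted by
#: the update operations: under ignorance the likelihood ratio is 1
#: regardless, so no prediction depends on this choice.
DEFAULT_IGNORANT_MARGINAL: Mapping[Statement, float] = MappingProxyType(
    {Statement.CORRECT: 0.0, Statement.INCORRECT: 0.0, Statement.NEUTRAL: 1.0}
)


@dataclass(frozen=True)
class BeliefState:
    """Learner's probability that her initial guess matches the true state.

    The prior defaults to 0.5: two cups, no a priori preference.
    """

    p_correct: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p_correct) and 0.0 <= self.p_correct <= 1.0):
            raise ParameterError(f"p_correct must be in [0, 1], got {self.p_correct!r}")

    @property
    def odds(self) -> float:
        """Odds correct : incorrect; ``inf`` at certainty."""
        if self.p_correct == 1.0:
            return math.inf
        return self.p_correct / (1.0 - self.p_correct)


class RuleKind(enum.Enum):
    MAXIMIZE = "maximize"
    PROBABILITY_MATCHING = "probability_matching"
    SOFTMAX = "softmax"


@dataclass(frozen=True)
class SwitchRule:
    """Decision rule mapping posterior belief to the probability of switching.

    The underlying account does not commit to a particular belief-to-choice
    link, so the rule is explicit:

    * ``maximize`` — switch iff the posterior favors the other option;
      exactly at 0.5 the learner stays (a tie-break that mirrors the
      observed tendency to stick with an initial answer under ignorance).
    * ``probability_matching`` — switch with probability equal to the
      posterior probability the initial guess is wrong.
    * ``softmax`` — a smooth compromise with inverse softness
      ``temperature``; switch prob = 1 / (1 + exp((2 p_correct - 1) / T)).

    Every rule output is lapse-mixed: with probability ``lapse`` the learner
    responds at random, so the effective switch probability is
    ``(1 - lapse) * rule_output + lapse * 0.5``.
    """

    kind: RuleKind = RuleKind.PROBABILITY_MATCHING
    temperature: float | None = None
    lapse: float = 0.0

    def __post_init__(self) -> None:
        kind = self.kind
        if isinstance(kind, str):  # tolerate plain strings from configs
            try:
                kind = RuleKind(kind)
            except ValueError as exc:
                raise ParameterError(f"unknown rule kind {self.kind!r}") from exc
            object.__setattr__(self, "kind", kind)
        if not (math.isfinite(self.lapse) and 0.0 <= self.lapse <= 1.0):
            raise ParameterError(f"lapse must be in [0, 1], got {self.lapse!r}")
        if self.kind is RuleKind.SOFTMAX:
            if self.temperature is None or not (
                math.isfinite(self.temperature) and self.temperature > 0.0
            ):
                raise ParameterError(
                    f"softmax requires temperature > 0, got {self.temperature!r}"
                )

    def to_dict(self) -> dict:
        d: dict = {"rule": self.kind.value, "lapse": self.lapse}
        if self.temperature is not None:
            d["temperature"] = self.temperature
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SwitchRule":
        return cls(
            kind=RuleKind(d.get("rule", "probability_matching")),
            temperature=d.get("temperature"),
            lapse=float(d.get("lapse", 0.0)),
        )


def statement_likelihood(
    guess_correct: bool,
    statement: Statement,
    knowledge: Knowledge,
    params: FeedbackParams,
    ignorant_marginal: Mapping[Statement, float] | None = None,
) -> float:
    """Probability of ``statement`` given the correctness of the guess.

    For a knowledgeable informant this reads the conditional statement
    table.  For an ignorant informant the world state does not influence the
    statement, so the returned probability is identical for
    ``guess_correct`` true and false; the marginal used defaults to
    :data:`DEFAULT_IGNORANT_MARGINAL`.
    """
    if knowledge is Knowledge.IGNORANT:
        marginal = DEFAULT_IGNORANT_MARGINAL if ignorant_marginal is None else ignorant_marginal
        p = float(marginal.get(statement, 0.0))
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"ignorant marginal probability out of range: {p}")
        return p
    if guess_correct:
        row = {
            Statement.CORRECT: params.alpha_c,
            Statement.INCORRECT: params.beta_c,
            Statement.NEUTRAL: params.neutral_given_correct,
        }
    else:
        row = {
            Statement.CORRECT: params.alpha_i,
            Statement.INCORRECT: params.beta_i,
            Statement.NEUTRAL: params.neutral_given_incorrect,
        }
    return row[statement]


def posterior_odds(
    params: FeedbackParams,
    statement: Statement,
    knowledge: Knowledge,
    prior_odds: float = 1.0,
    ignorant_marginal: Mapping[Statement, float] | None = None,
) -> float:
    """Posterior odds (correct : incorrect of the initial guess) after a statement.

    Bayes rule in odds form: posterior odds = prior odds x likelihood ratio.
    Under ignorance the likelihood ratio is exactly 1, so the prior odds are
    returned unchanged (provided the statement is possible at all under the
    ignorant marginal).  Odds below 1 mean the statement is evidence that
    the initial guess was wrong.
    """
    if not (math.isfinite(prior_odds) and prior_odds > 0.0):
        raise ParameterError(f"prior_odds must be positive and finite, got {prior_odds!r}")
    if knowledge is Knowledge.IGNORANT:
        p = statement_likelihood(True, statement, knowledge, params, ignorant_marginal)
        if p == 0.0:
            raise ImpossibleEvidenceError(
                f"statement {statement.value!r} has zero probability under the "
                "ignorant informant's marginal"
            )
        return prior_odds
    lik_correct = statement_likelihood(True, statement, knowledge, params)
    lik_incorrect = statement_likelihood(False, statement, knowledge, params)
    if lik_correct == 0.0 and lik_incorrect == 0.0:
        raise ImpossibleEvidenceError(
            f"statement {statement.value!r} has zero likelihood under both hypotheses"
        )
    if lik_incorrect == 0.0:
        return math.inf
    return prior_odds * lik_correct / lik_incorrect


def posterior_belief(
    prior: BeliefState,
    statement: Statement,
    knowledge: Knowledge,
    params: FeedbackParams,
    ignorant_marginal: Mapping[Statement, float] | None = None,
) -> BeliefState:
    """Update the learner's belief that her initial guess is correct.

    Degenerate priors are absorbing: a learner certain either way stays
    certain as long as the statement is possible under her hypothesis.
    """
    p = prior.p_correct
    if p == 1.0 or p == 0.0:
        lik = statement_likelihood(p == 1.0, statement, knowledge, params, ignorant_marginal)
        other = statement_likelihood(p != 1.0, statement, knowledge, params, ignorant_marginal)
        if lik == 0.0 and other == 0.0:
            raise ImpossibleEvidenceError(
                f"statement {statement.value!r} has zero likelihood under both hypotheses"
            )
        if lik == 0.0:
            # all prior mass on a hypothesis that cannot produce the statement
            raise ImpossibleEvidenceError(
                f"statement {statement.value!r} is impossible under the learner's "
                "certain belief"
            )
        return prior
    if knowledge is Knowledge.IGNORANT:
        # likelihood ratio is exactly 1: avoid odds round-trip float noise
        posterior_odds(params, statement, knowledge, 1.0, ignorant_marginal)
        return prior
    odds = posterior_odds(params, statement, knowledge, p / (1.0 - p), ignorant_marginal)
    if math.isinf(odds):
        return BeliefState(1.0)
    return BeliefState(odds / (1.0 + odds))


def classify_regime(params: FeedbackParams, tol: float = 1e-9) -> Regime:
    """Classify the informant's feedback bias from ``alpha_c`` vs ``beta_i``.

    ``alpha_c > beta_i`` (beyond ``tol``) is the positivity-bias regime:
    praise for correct answers is more probable than censure for incorrect
    ones, so a neutral query from a knowledgeable informant favors
    switching.  ``alpha_c < beta_i`` reverses the prediction; within ``tol``
    the informant is unbiased and the neutral query is uninformative.
    """
    if tol < 0:
        raise ParameterError(f"tol must be nonnegative, got {tol!r}")
    diff = params.alpha_c - params.beta_i
    if abs(diff) <= tol:
        return Regime.UNBIASED
    return Regime.POSITIVE if diff > 0 else Regime.NEGATIVE


def switch_probability(belief: BeliefState, rule: SwitchRule) -> float:
    """Probability that the learner abandons her initial guess.

    The raw rule output is computed from the posterior belief and then
    lapse-mixed with chance responding (0.5).
    """
    p = belief.p_correct
    if rule.kind is RuleKind.MAXIMIZE:
        raw = 1.0 if p < 0.5 else 0.0  # tie at 0.5 -> stay
    elif rule.kind is RuleKind.PROBABILITY_MATCHING:
        raw = 1.0 - p
    else:  # softmax
        raw = 1.0 / (1.0 + math.exp((2.0 * p - 1.0) / rule.temperature))
    return (1.0 - rule.lapse) * raw + rule.lapse * 0.5


def predicted_switch_probability(
    params: FeedbackParams,
    knowledge: Knowledge,
    rule: SwitchRule,
    prior: BeliefState | None = None,
) -> float:
    """Model-predicted switch probability after a neutral query.

    Convenience composition of :func:`posterior_belief` (on the neutral
    statement) and :func:`switch_probability`, from an optional prior
    (default: indifference).
    """
    prior = BeliefState() if prior is None else prior
    post = posterior_belief(prior, Statement.NEUTRAL, knowledge, params)
    return switch_probability(post, rule)
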