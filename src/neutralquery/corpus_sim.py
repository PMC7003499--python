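"""Synthetic coded parent-child exchanges and their summary statistics.

Real corpora of home conversations show that when a mother follows up a
child's answer at all, praise vastly outnumbers censure, and neutral
re-queries ("are you sure?", repeating the question) disproportionately
follow *incorrect* answers.  This module emulates the coded output of that
style of analysis — not the transcripts themselves: each record is one
question that a child answered, with flags for whether a follow-up
occurred, whether the answer was independently verifiable, whether it was
correct, and the follow-up category (positive / negative / neutral).

The generator's defaults are the observed coding rates: 226 of 732
answered questions drew a follow-up; 84 of those were verifiable, 64 of
the 84 correct; 59/64 correct answers drew praise and 5/64 a neutral
query, while 13/20 incorrect answers drew censure and 7/20 a neutral
query.  Non-verifiable follow-ups use the marginal category split
(144, 26, 56)/226, which is not stratified by correctness.

:func:`estimate_feedback_params` closes the loop: it reads the empirical
feedback probabilities (``alpha_c = P(positive | correct)``,
``beta_i = P(negative | incorrect)``, ...) off a coded corpus, yielding the
:class:`~neutralquery.feedback_model.FeedbackParams` under which the belief
model predicts switching after a knowledgeable neutral query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exact_stats import Counts2x2
from .exceptions import DataError, InsufficientDataError, ParameterError
from .feedback_model import FeedbackParams

__all__ = [
    "FOLLOWUP_CATEGORIES",
    "CodedExchange",
    "CorpusParams",
    "FollowupSummary",
    "EmpiricalFeedback",
    "generate_corpus",
    "summarize_followups",
    "estimate_feedback_params",
    "corpus_to_frame",
    "frame_to_corpus",
    "write_corpus_csv",
    "read_corpus_csv",
]

#: Follow-up categories, in the fixed (positive, negative, neutral) order
#: used by every probability vector and count triple in this module.
FOLLOWUP_CATEGORIES = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class CodedExchange:
    """One coded question-answer-follow-up record.

    ``answer_correct`` is ``None`` unless the answer was independently
    verifiable; ``followup`` is ``"none"`` when the conversation moved on
    without any follow-up (the modal outcome).  Excluded follow-up types —
    repeating the child's answer as a question, clarification questions —
    are coded as ``"none"`` by construction.
    """

    exchange_id: str
    answered: bool
    answer_verifiable: bool
    answer_correct: bool | None
    followup: str

    def __post_init__(self) -> None:
        if self.followup not in FOLLOWUP_CATEGORIES + ("none",):
            raise ParameterError(f"bad followup category {self.followup!r}")
        if self.followup != "none" and not self.answered:
            raise ParameterError("follow-up recorded for an unanswered question")
        if (self.answer_correct is not None) != self.answer_verifiable:
            raise ParameterError(
                "answer_correct must be set exactly when the answer is verifiable"
            )


def _check_prob_vector(name: str, v: Sequence[float]) -> tuple[float, float, float]:
    vec = tuple(float(x) for x in v)
    if len(vec) != 3 or any(not (0.0 <= x <= 1.0) for x in vec):
        raise ParameterError(f"{name} must be 3 probabilities, got {v!r}")
    if abs(sum(vec) - 1.0) > 1e-9:
        raise ParameterError(f"{name} must sum to 1, got sum {sum(vec)}")
    return vec


@dataclass(frozen=True)
class CorpusParams:
    """Generating rates for a synthetic coded corpus.

    Defaults reproduce the observed coding rates (see module docstring);
    every rate is configurable.  Probability triples are ordered
    (positive, negative, neutral).
    """

    n_questions: int = 732
    p_followup: float = 226 / 732
    p_verifiable: float = 84 / 226
    p_correct_given_verifiable: float = 64 / 84
    followup_probs_given_correct: tuple[float, float, float] = (59 / 64, 0.0, 5 / 64)
    followup_probs_given_incorrect: tuple[float, float, float] = (0.0, 13 / 20, 7 / 20)
    followup_probs_nonverifiable: tuple[float, float, float] = (144 / 226, 26 / 226, 56 / 226)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_questions < 0:
            raise ParameterError(f"n_questions must be nonnegative, got {self.n_questions}")
        for name in ("p_followup", "p_verifiable", "p_correct_given_verifiable"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be a probability, got {v!r}")
        for name in (
            "followup_probs_given_correct",
            "followup_probs_given_incorrect",
            "followup_probs_nonverifiable",
        ):
            object.__setattr__(self, name, _check_prob_vector(name, getattr(self, name)))


def generate_corpus(params: CorpusParams) -> list[CodedExchange]:
    """Sample a synthetic coded corpus, deterministically given the seed.

    Per answered question: a follow-up occurs with ``p_followup``; followed-
    up answers are verifiable with ``p_verifiable``; verifiable answers are
    correct with ``p_correct_given_verifiable``; the follow-up category is
    then drawn from the corresponding conditional (or the non-verifiable
    marginal).  Empirical rates converge to the parameters as n grows.
    """
    n = params.n_questions
    rng = np.random.default_rng(params.seed)
    if n == 0:
        return []
    followed = rng.random(n) < params.p_followup
    verifiable = followed & (rng.random(n) < params.p_verifiable)
    correct = verifiable & (rng.random(n) < params.p_correct_given_verifiable)
    u = rng.random(n)

    def pick(probs: tuple[float, float, float], x: float) -> str:
        acc = 0.0
        for cat, p in zip(FOLLOWUP_CATEGORIES, probs):
            acc += p
            if x < acc:
                return cat
        return FOLLOWUP_CATEGORIES[-1]

    out: list[CodedExchange] = []
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        if not followed[i]:
            cat = "none"
        elif verifiable[i]:
            probs = (
                params.followup_probs_given_correct
                if correct[i]
                else params.followup_probs_given_incorrect
            )
            cat = pick(probs, u[i])
        else:
            cat = pick(params.followup_probs_nonverifiable, u[i])
        out.append(
            CodedExchange(
                exchange_id=f"q{i:0{width}d}",
                answered=True,
                answer_verifiable=bool(verifiable[i]),
                answer_correct=bool(correct[i]) if verifiable[i] else None,
                followup=cat,
            )
        )
    return out


@dataclass(frozen=True)
class FollowupSummary:
    """Counts of follow-up categories and the verifiable 2x2 cross-table.

    ``verifiable_table`` crosses answer correctness (rows: correct,
    incorrect) with neutral vs non-neutral follow-up (columns: neutral,
    other) among verifiable answers that received a follow-up; ``None``
    when that stratum is empty.
    """

    n_exchanges: int
    n_followed: int
    positive: int
    negative: int
    neutral: int
    verifiable_table: Counts2x2 | None

    @property
    def followup_counts(self) -> tuple[int, int, int]:
        return (self.positive, self.negative, self.neutral)


def summarize_followups(corpus: Sequence[CodedExchange]) -> FollowupSummary:
    """Tally follow-up categories; order of the corpus is irrelevant.

    The three category counts sum to the number of followed-up exchanges.
    """
    counts = {cat: 0 for cat in FOLLOWUP_CATEGORIES}
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    n_verifiable_followed = 0
    for ex in corpus:
        if ex.followup == "none":
            continue
        counts[ex.followup] += 1
        if ex.answer_verifiable:
            n_verifiable_followed += 1
            cells[(bool(ex.answer_correct), ex.followup == "neutral")] += 1
    table = None
    if n_verifiable_followed > 0:
        table = Counts2x2.from_rows(
            (cells[(True, True)], cells[(True, False)]),
            (cells[(False, True)], cells[(False, False)]),
        )
    return FollowupSummary(
        n_exchanges=len(corpus),
        n_followed=sum(counts.values()),
        positive=counts["positive"],
        negative=counts["negative"],
        neutral=counts["neutral"],
        verifiable_table=table,
    )


@dataclass(frozen=True)
class EmpiricalFeedback:
    """Feedback parameters estimated from a coded corpus, with the counts
    behind them so standard errors can be formed."""

    params: FeedbackParams
    n_correct: int
    n_incorrect: int
    counts_correct: dict = field(default_factory=dict)
    counts_incorrect: dict = field(default_factory=dict)


def estimate_feedback_params(corpus: Sequence[CodedExchange]) -> EmpiricalFeedback:
    """Estimate the informant's feedback probabilities from coded exchanges.

    Uses verifiable answers that received a follow-up:
    ``alpha_c = P(positive | correct)``, ``beta_c = P(negative | correct)``,
    ``alpha_i = P(positive | incorrect)``, ``beta_i = P(negative | incorrect)``.
    Requires at least one followed-up verifiable answer in each correctness
    stratum.
    """
    counts_c = {cat: 0 for cat in FOLLOWUP_CATEGORIES}
    counts_i = {cat: 0 for cat in FOLLOWUP_CATEGORIES}
    for ex in corpus:
        if ex.followup == "none" or not ex.answer_verifiable:
            continue
        (counts_c if ex.answer_correct else counts_i)[ex.followup] += 1
    n_c, n_i = sum(counts_c.values()), sum(counts_i.values())
    if n_c == 0 or n_i == 0:
        raise InsufficientDataError(
            "need at least one followed-up verifiable answer in each of the "
            f"correct/incorrect strata (got {n_c} correct, {n_i} incorrect)"
        )
    params = FeedbackParams(
        alpha_c=counts_c["positive"] / n_c,
        beta_c=counts_c["negative"] / n_c,
        alpha_i=counts_i["positive"] / n_i,
        beta_i=counts_i["negative"] / n_i,
    )
    return EmpiricalFeedback(
        params=params,
        n_correct=n_c,
        n_incorrect=n_i,
        counts_correct=counts_c,
        counts_incorrect=counts_i,
    )


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = ["exchange_id", "answered", "answer_verifiable", "answer_correct", "followup"]


def corpus_to_frame(corpus: Sequence[CodedExchange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exchange_id": ex.exchange_id,
                "answered": ex.answered,
                "answer_verifiable": ex.answer_verifiable,
                "answer_correct": ex.answer_correct,
                "followup": ex.followup,
            }
            for ex in corpus
        ],
        columns=_CSV_COLUMNS,
    )


def frame_to_corpus(frame: pd.DataFrame) -> list[CodedExchange]:
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples():
        correct = row.answer_correct
        if correct is None or (isinstance(correct, float) and math.isnan(correct)):
            correct = None
        else:
            correct = bool(correct)
        out.append(
            CodedExchange(
                exchange_id=str(row.exchange_id),
                answered=bool(row.answered),
                answer_verifiable=bool(row.answer_verifiable),
                answer_correct=correct,
                followup=str(row.followup),
            )
        )
    return out


def write_corpus_csv(corpus: Sequence[CodedExchange], path) -> None:
    corpus_to_frame(corpus).to_csv(path, index=False)


def read_corpus_csv(path) -> list[CodedExchange]:
    return frame_to_corpus(pd.read_csv(path))
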