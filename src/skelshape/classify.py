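"""Classification scores from habituation-normalized responses.

Works identically for infant looking times (seconds) and model
reconstruction errors (error units): responses to the test objects are
normalized by subtracting the mean response over the last four habituation
trials/epochs, negatives are clipped at zero, and the novel response is
expressed as a proportion of the combined novel + familiar response.  0.50
is chance; scores above 0.50 indicate classification of the novel object as
more different.  Uncertainty comes from a percentile bootstrap over units
(infants, or habituation-object runs for models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NormalizedResponse",
    "ClassificationScore",
    "normalize_response",
    "classification_score",
    "bootstrap_ci",
    "above_chance",
    "score_units",
]


@dataclass(frozen=True)
class NormalizedResponse:
    """Response minus the mean of the last four habituation trials/epochs."""

    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("normalized response must be finite")


def normalize_response(response: float, habituation_tail: Sequence[float]) -> NormalizedResponse:
    """Difference between a test response and the end-of-habituation level
    (mean of exactly the last four habituation values)."""
    tail = np.asarray(list(habituation_tail), dtype=float)
    if tail.shape != (4,):
        raise ValueError(f"habituation tail must hold exactly 4 values, got {tail.shape}")
    return NormalizedResponse(value=float(response - tail.mean()))


def classification_score(novel, familiar) -> float:
    """novel / (novel + familiar) on clipped normalized responses.

    Negative normalized responses (responses below the end-of-habituation
    level) are clipped to 0 so the score stays in [0, 1]; if both clip to 0
    the score is 0.5 (no evidence either way).
    """
    nv = novel.value if isinstance(novel, NormalizedResponse) else float(novel)
    fv = familiar.value if isinstance(familiar, NormalizedResponse) else float(familiar)
    nv, fv = max(nv, 0.0), max(fv, 0.0)
    if nv + fv == 0:
        return 0.5
    return nv / (nv + fv)


def bootstrap_ci(unit_scores: Sequence[float], iterations: int = 5000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-unit scores."""
    x = np.asarray(list(unit_scores), dtype=float)
    if x.size == 0:
        raise ValueError("unit_scores must be nonempty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(iterations, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return (float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha)))


def above_chance(ci: tuple[float, float]) -> bool:
    """True iff the whole confidence interval lies strictly above 0.50."""
    return ci[0] > 0.5


@dataclass
class ClassificationScore:
    """Mean per-unit classification score with bootstrap CI."""

    score: float
    n_units: int
    ci_low: float
    ci_high: float
    unit_scores: tuple = ()

    @property
    def above_chance(self) -> bool:
        return self.ci_low > 0.5


def score_units(novel_responses: Sequence[float], familiar_responses: Sequence[float],
                iterations: int = 5000, seed: int = 0) -> ClassificationScore:
    """Per-unit scores from paired normalized (already tail-subtracted)
    novel/familiar responses, aggregated with a bootstrap CI."""
    nv = np.asarray(list(novel_responses), dtype=float)
    fv = np.asarray(list(familiar_responses), dtype=float)
    if nv.shape != fv.shape or nv.size == 0:
        raise ValueError("novel and familiar response lists must match and be nonempty")
    units = [classification_score(a, b) for a, b in zip(nv, fv)]
    if len(units) > 1:
        lo, hi = bootstrap_ci(units, iterations=iterations, seed=seed)
    else:
        lo = hi = units[0]
    return ClassificationScore(score=float(np.mean(units)), n_units=len(units),
                               ci_low=lo, ci_high=hi, unit_scores=tuple(units))
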