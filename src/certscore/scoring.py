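"""Composite error score and correctness classification.

Each certificate's score is ``2 * (number of major error types present) +
1 * (number of minor error types present)``; a certificate is *correct* when
no error type is present. Each error type contributes at most once however
many lines exhibit it, so the score lies in 0..11 (4 majors, 3 minors).
Weights are configurable for sensitivity analysis only; the default weights
are the assessment tool's.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rules import ERROR_TYPES, MAJOR_ERRORS, MINOR_ERRORS, ErrorProfile

#: Error-count bands used in correctness tabulations (top band open-ended).
COUNT_BANDS = ("0", "1", "2", "3", "4+")


@dataclass(frozen=True)
class ScoreResult:
    n_major: int
    n_minor: int
    score: int
    correct: bool

    @property
    def n_errors(self) -> int:
        return self.n_major + self.n_minor


def score_profile(
    profile: ErrorProfile, *, major_weight: int = 2, minor_weight: int = 1
) -> ScoreResult:
    """Score one error profile."""
    n_major = sum(getattr(profile, name) for name in MAJOR_ERRORS)
    n_minor = sum(getattr(profile, name) for name in MINOR_ERRORS)
    return ScoreResult(
        n_major=n_major,
        n_minor=n_minor,
        score=major_weight * n_major + minor_weight * n_minor,
        correct=(n_major + n_minor) == 0,
    )


def score_batch(profiles, **weights) -> list[ScoreResult]:
    return [score_profile(p, **weights) for p in profiles]


def error_count_band(result: ScoreResult | int) -> str:
    """Band the number of error types: 0, 1, 2, 3 or 4+."""
    n = result if isinstance(result, int) else result.n_errors
    if n < 0:
        raise ValueError("error count must be non-negative")
    return COUNT_BANDS[n] if n < 4 else "4+"


__all__ = ["COUNT_BANDS", "ScoreResult", "error_count_band", "score_batch", "score_profile"]
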