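"""Length-of-stay to patient-satisfaction scoring.

Domain experts (the department chief and senior nurses) describe, for each
patient type, an optimistic / most-likely / pessimistic length of stay (LOS,
minutes) and the satisfaction score (%) attached to each — triangular
elicitations.  A patient's simulated LOS is standardized by the LOS mean and
SD and then mapped onto the score scale by the score mean and SD, with longer
stays always scoring lower, clamped to [0, 100].

By default the means and SDs are the closed-form moments of the elicited
triangular distributions; user-supplied empirical (mean, SD) pairs are also
accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TriangularSpec",
    "SatisfactionProfile",
    "ScoreMapping",
    "DegenerateTriangularError",
    "tri_mean",
    "tri_sd",
    "los_to_score",
    "average_satisfaction",
    "DEFAULT_PROFILES",
]


class DegenerateTriangularError(ValueError):
    """All three triangular parameters coincide: the mapping is undefined."""


@dataclass(frozen=True)
class TriangularSpec:
    """Expert triangular elicitation: optimistic / most likely / pessimistic.

    For LOS the optimistic value is the smallest; for scores it is the
    largest.  Moments are computed on the sorted parameters, so either
    orientation is accepted.
    """

    optimistic: float
    most_likely: float
    pessimistic: float

    def sorted_params(self) -> tuple[float, float, float]:
        a, m, b = sorted((self.optimistic, self.most_likely, self.pessimistic))
        return a, m, b

    @property
    def is_degenerate(self) -> bool:
        a, m, b = self.sorted_params()
        return a == m == b


def tri_mean(spec: TriangularSpec) -> float:
    """(a + m + b) / 3 on the sorted parameters."""
    a, m, b = spec.sorted_params()
    return (a + m + b) / 3.0


def tri_sd(spec: TriangularSpec) -> float:
    """sqrt((a^2 + m^2 + b^2 - am - ab - mb) / 18); 0 for a degenerate spec."""
    a, m, b = spec.sorted_params()
    var = (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class SatisfactionProfile:
    """Per-patient-type pairing of a LOS elicitation (minutes) and a score
    elicitation (percent, within [0, 100])."""

    ptype: int
    los_tri: TriangularSpec
    score_tri: TriangularSpec

    def __post_init__(self) -> None:
        lo = self.los_tri
        if not (lo.optimistic <= lo.most_likely <= lo.pessimistic):
            raise ValueError(
                f"type {self.ptype}: LOS elicitation must be nondecreasing "
                f"(optimistic <= most likely <= pessimistic)"
            )
        sc = self.score_tri
        if not (sc.optimistic >= sc.most_likely >= sc.pessimistic):
            raise ValueError(
                f"type {self.ptype}: score elicitation must be nonincreasing"
            )
        for v in (sc.optimistic, sc.most_likely, sc.pessimistic):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"type {self.ptype}: scores must lie in [0, 100]")


@dataclass(frozen=True)
class ScoreMapping:
    """Standardization constants mapping LOS (min) onto the score scale (%).

    ``source`` records whether the constants are triangular moments of an
    elicited profile or externally supplied empirical statistics.
    """

    mean_los: float
    sd_los: float
    mean_score: float
    sd_score: float
    source: str = "triangular_moments"

    def __post_init__(self) -> None:
        if self.sd_los <= 0 or self.sd_score <= 0:
            raise DegenerateTriangularError(
                "score mapping needs strictly positive LOS and score SDs"
            )

    @classmethod
    def from_profile(cls, profile: SatisfactionProfile) -> "ScoreMapping":
        if profile.los_tri.is_degenerate or profile.score_tri.is_degenerate:
            raise DegenerateTriangularError(
                f"type {profile.ptype}: degenerate triangular elicitation"
            )
        return cls(
            mean_los=tri_mean(profile.los_tri),
            sd_los=tri_sd(profile.los_tri),
            mean_score=tri_mean(profile.score_tri),
            sd_score=tri_sd(profile.score_tri),
            source="triangular_moments",
        )

    @classmethod
    def empirical(
        cls, mean_los: float, sd_los: float, mean_score: float, sd_score: float
    ) -> "ScoreMapping":
        return cls(mean_los, sd_los, mean_score, sd_score, source="empirical")


def los_to_score(mapping: ScoreMapping, los: float) -> float:
    """Map one LOS (minutes) to a satisfaction score in [0, 100].

    score = mean_score - sd_score * (los - mean_los) / sd_los, clamped.
    Strictly decreasing in LOS inside the clamp region: a longer stay never
    scores higher.
    """
    if los < 0:
        raise ValueError("LOS cannot be negative")
    z = (los - mapping.mean_los) / mapping.sd_los
    score = mapping.mean_score - mapping.sd_score * z
    return min(100.0, max(0.0, score))


def average_satisfaction(patients: Iterable) -> float:
    """Arithmetic mean of per-patient scores, in percent.

    Accepts either patient records carrying a ``score`` attribute or bare
    numbers.  An empty collection is an error — the objective is undefined
    for a day with no patients.
    """
    scores = [getattr(p, "score", p) for p in patients]
    if not scores:
        raise ValueError("average satisfaction undefined for an empty patient set")
    if any(s is None for s in scores):
        raise ValueError("some patients have no satisfaction score attached")
    return float(sum(scores) / len(scores))


def triangular_inverse_cdf(a: float, m: float, b: float, u: float) -> float:
    """Inverse CDF of the triangular(a, m, b) distribution at u in [0, 1]."""
    if not (a <= m <= b):
        raise ValueError("triangular parameters must satisfy a <= m <= b")
    if b == a:
        return a
    fc = (m - a) / (b - a)
    if u < fc:
        return a + math.sqrt(u * (b - a) * (m - a))
    return b - math.sqrt((1.0 - u) * (b - a) * (b - m))


def _profile(ptype: int, los: Sequence[float], score: Sequence[float]) -> SatisfactionProfile:
    return SatisfactionProfile(
        ptype=ptype,
        los_tri=TriangularSpec(*los),
        score_tri=TriangularSpec(*score),
    )


#: Default expert elicitations, one per patient type: (optimistic, most
#: likely, pessimistic) LOS in minutes against (100, 75, 50) percent.
DEFAULT_PROFILES: dict[int, SatisfactionProfile] = {
    1: _profile(1, (55.0, 90.0, 120.0), (100.0, 75.0, 50.0)),
    2: _profile(2, (15.0, 30.0, 60.0), (100.0, 75.0, 50.0)),
    3: _profile(3, (45.0, 70.0, 90.0), (100.0, 75.0, 50.0)),
    4: _profile(4, (45.0, 70.0, 90.0), (100.0, 75.0, 50.0)),
}
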