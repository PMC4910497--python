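"""Confidence scoring: match features -> points -> sigmoid confidence.

Even a perfect string match can be the wrong taxon (homonyms), and a
fuzzy match can be pure noise, so every cross-mapping result carries a
confidence in (0, 1).  Points are added for features that make a correct
match more likely (deeper matched rank, agreeing authorship) and
subtracted for features that make it less likely (authorship conflict,
edit distance, multiple tied targets).  The point total p is squashed
through a base-3 logistic

    confidence = 1 / (1 + 3**(-p))

so that 0 points is neutral (0.5) and strong evidence saturates near 1.
Results at or below 0.5 need to be confirmed by a human check.

The weights are calibrated, not first-principles: with the defaults a
bare uninomial exact match (1 point) gives 0.75, a binomial canonical
match (4 points) gives 0.988, agreeing full authorship lifts that to
0.999, a conflicting authorship drops it back to 0.75, and each edit of
distance costs 2 points so an edit-distance-2 binomial sits exactly on
the 0.5 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config import load_yaml

RANK_UNINOMIAL = "uninomial"
RANK_BINOMIAL = "binomial"
RANK_TRINOMIAL_PLUS = "trinomial_plus"

AUTHORSHIP_ABSENT = "absent"
AUTHORSHIP_AGREES = "agrees"
AUTHORSHIP_CONFLICTS = "conflicts"


@dataclass(frozen=True)
class MatchFeatures:
    matched_rank: str = RANK_BINOMIAL
    authorship_state: str = AUTHORSHIP_ABSENT
    edit_distance: int = 0
    multi_target: bool = False


@dataclass(frozen=True)
class ConfidenceScore:
    points: float
    confidence: float
    needs_human_check: bool


@dataclass(frozen=True)
class ScoringWeights:
    sigmoid_base: float = 3.0
    uninomial: float = 1.0
    binomial: float = 4.0
    trinomial_plus: float = 4.0
    authorship_agrees: float = 2.3
    authorship_conflicts: float = -3.0
    per_edit: float = -2.0
    multi_target: float = -1.0
    human_check_threshold: float = 0.5

    @classmethod
    def from_config(cls, path: Optional[str] = None) -> "ScoringWeights":
        raw = load_yaml(path, "scoring.yaml")
        pts = raw["points"]
        return cls(
            sigmoid_base=float(raw["sigmoid_base"]),
            uninomial=float(pts["uninomial"]),
            binomial=float(pts["binomial"]),
            trinomial_plus=float(pts["trinomial_plus"]),
            authorship_agrees=float(pts["authorship_agrees"]),
            authorship_conflicts=float(pts["authorship_conflicts"]),
            per_edit=float(pts["per_edit"]),
            multi_target=float(pts["multi_target"]),
            human_check_threshold=float(raw["human_check_threshold"]),
        )


DEFAULT_WEIGHTS = ScoringWeights()


def points_for(features: MatchFeatures, weights: ScoringWeights = DEFAULT_WEIGHTS) -> float:
    """Sum the point contributions of the match features."""
    rank_points = {
        RANK_UNINOMIAL: weights.uninomial,
        RANK_BINOMIAL: weights.binomial,
        RANK_TRINOMIAL_PLUS: weights.trinomial_plus,
    }
    points = rank_points[features.matched_rank]
    if features.authorship_state == AUTHORSHIP_AGREES:
        points += weights.authorship_agrees
    elif features.authorship_state == AUTHORSHIP_CONFLICTS:
        points += weights.authorship_conflicts
    points += weights.per_edit * features.edit_distance
    if features.multi_target:
        points += weights.multi_target
    return points


def sigmoid(points: float, base: float = 3.0) -> float:
    """Logistic squash of a point total into (0, 1); sigmoid(0) = 0.5."""
    if points >= 0:
        return 1.0 / (1.0 + base ** (-points))
    # evaluate from the other side to avoid overflow for large negatives
    e = base ** points
    return e / (1.0 + e)


def score(features: MatchFeatures, weights: ScoringWeights = DEFAULT_WEIGHTS) -> ConfidenceScore:
    """Full pipeline: features -> points -> confidence -> human-check flag."""
    pts = points_for(features, weights)
    conf = sigmoid(pts, weights.sigmoid_base)
    return ConfidenceScore(
        points=pts,
        confidence=conf,
        needs_human_check=conf <= weights.human_check_threshold,
    )
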