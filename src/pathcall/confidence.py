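"""Three-tier confidence classification of step candidates.

A candidate found by sequence search is **high** confidence when it is at
least 40% identical to a characterized protein with at least 80% coverage
of it, and it is more similar (by bit score, strictly) to proteins known to
perform the step than to characterized proteins with other functions.
Otherwise it is **medium** when it is at least 30% identical with 80%
coverage and not out-scored by an other-function protein, or at least 40%
identical with 70% coverage regardless of other-function similarity.
Everything else is **low**.

A candidate found by profile-HMM search is high confidence when the
alignment covers 80% of the model and the protein is not too similar to
proteins with other functions (no other-function alignment at 40% identity
and 80% coverage); any other reported HMM hit is medium (the tool defines
only the high case; sub-threshold hits that still pass the reporting
E-value are treated as suggestive, not strong, evidence).

A step with no candidates at all is low confidence; it still participates
in path scoring so that every path is comparable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from .homology import Alignment, HmmHit

__all__ = [
    "Confidence",
    "ConfidenceThresholds",
    "Candidate",
    "classify_sequence_evidence",
    "classify_hmm_evidence",
    "combine_evidence",
    "step_confidence",
]


class Confidence(enum.IntEnum):
    """Ordered confidence classes; the int value doubles as the category."""

    low = 0
    medium = 1
    high = 2

    def __str__(self) -> str:  # TSV-friendly
        return self.name


@dataclass
class ConfidenceThresholds:
    hi_identity: float = 0.40
    hi_coverage: float = 0.80
    med_identity: float = 0.30
    med_coverage: float = 0.80
    med_alt_identity: float = 0.40
    med_alt_coverage: float = 0.70
    hmm_hi_model_coverage: float = 0.80
    otherfn_identity: float = 0.40
    otherfn_coverage: float = 0.80

    def __post_init__(self):
        for name, v in vars(self).items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        if self.hi_identity < self.med_identity:
            raise ValueError("hi_identity must be >= med_identity")


@dataclass
class Candidate:
    """One proteome protein's combined evidence for one step."""

    protein_id: str
    step_id: str
    evidence: str  # "sequence", "hmm", or "both"
    best_same_step: Optional[Alignment] = None
    best_hmm: Optional[HmmHit] = None
    best_other_function: Optional[Alignment] = None
    confidence: Confidence = Confidence.low


def _outscored(hit: Alignment, other: Optional[Alignment]) -> bool:
    # "more similar" means strictly greater bit score; ties demote.
    return other is not None and hit.bits <= other.bits


def classify_sequence_evidence(
    hit: Alignment,
    other: Optional[Alignment],
    t: ConfidenceThresholds | None = None,
) -> Confidence:
    """Classify a sequence-search candidate against one step.

    ``hit`` is the best alignment to a protein known to perform the step;
    ``other`` the best alignment to a characterized protein with another
    function (ignore-listed proteins excluded upstream).
    """
    t = t or ConfidenceThresholds()
    outscored = _outscored(hit, other)
    if (
        hit.identity >= t.hi_identity
        and hit.subject_coverage >= t.hi_coverage
        and not outscored
    ):
        return Confidence.high
    if (
        hit.identity >= t.med_identity
        and hit.subject_coverage >= t.med_coverage
        and not outscored
    ):
        return Confidence.medium
    if hit.identity >= t.med_alt_identity and hit.subject_coverage >= t.med_alt_coverage:
        return Confidence.medium
    return Confidence.low


def classify_hmm_evidence(
    hit: HmmHit,
    other: Optional[Alignment],
    t: ConfidenceThresholds | None = None,
) -> Confidence:
    """Classify a profile-HMM candidate: high on 80% model coverage unless
    an other-function protein aligns at 40% identity and 80% coverage."""
    t = t or ConfidenceThresholds()
    disqualified = (
        other is not None
        and other.identity >= t.otherfn_identity
        and other.subject_coverage >= t.otherfn_coverage
    )
    if hit.model_coverage >= t.hmm_hi_model_coverage and not disqualified:
        return Confidence.high
    return Confidence.medium


def combine_evidence(
    seq_conf: Optional[Confidence], hmm_conf: Optional[Confidence]
) -> Confidence:
    """Max of the available evidence classes (low < medium < high)."""
    present = [c for c in (seq_conf, hmm_conf) if c is not None]
    if not present:
        raise ValueError("no evidence to combine")
    return max(present)


def step_confidence(candidates: Iterable[Candidate]) -> Confidence:
    """Best candidate confidence; low when the step has no candidates."""
    return max((c.confidence for c in candidates), default=Confidence.low)
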