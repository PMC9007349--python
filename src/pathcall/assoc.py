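"""Evaluation computations: Fisher-exact trait association, profile-HMM
family presence with competing-model exclusion, and the leave-one-out
best-hit threshold benchmark.

These support the comparative analyses around pathway annotation: e.g.
asking whether a protein family (called present in a genome by hmmsearch
against its model at the trusted cutoff, ignoring proteins that score
higher against a competing family's model) is enriched among genomes of
organisms reported to utilize a compound, and measuring how often a best
homology hit at the high-confidence thresholds actually shares the
annotated step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .curated import CuratedProtein
from .homology import _name, align_pair, hmm_search

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "PresenceCall",
    "fisher_exact_2x2",
    "family_presence",
    "trait_association",
    "loo_threshold_accuracy",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: row 1 = group of interest with/without the trait, row 2 =
    comparison group with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def row_swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float  # may be inf/0 for degenerate margins
    p_two_sided: float


@dataclass(frozen=True)
class PresenceCall:
    genome_id: str
    family_id: str
    present: bool
    best_bits: Optional[float] = None


def fisher_exact_2x2(t: ContingencyTable2x2) -> OddsRatioResult:
    """Sample odds ratio (a/b)/(c/d) and exact two-sided p.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's. A zero margin row or column makes the test degenerate and is
    an error; a single zero cell yields an infinite or zero odds ratio.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin (row or column) is all zero")
    if b == 0 or c == 0:
        odds_ratio = math.inf
    elif a == 0 or d == 0:
        odds_ratio = 0.0
    else:
        odds_ratio = (a / b) / (c / d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OddsRatioResult(odds_ratio=odds_ratio, p_two_sided=float(p))


def family_presence(
    proteome: Sequence[tuple[str, str]],
    target_model,
    competitor_models: Sequence = (),
    *,
    genome_id: str = "genome",
    bit_threshold: float | None = None,
    max_evalue: float = 10.0,
) -> PresenceCall:
    """Call a protein family present in a genome, excluding proteins that
    match a competing family better.

    The family is present when some protein scores at or above the model's
    trusted cutoff (or an explicit ``bit_threshold``) against the target
    model AND its target bits exceed its bits against every competitor
    model. ``best_bits`` is the best qualifying target score.
    """
    target_hits = hmm_search(proteome, target_model, max_evalue=max_evalue)
    if bit_threshold is not None:
        cutoff = bit_threshold
    else:
        tc = next((h.trusted_cutoff for h in target_hits), None)
        if target_model.cutoffs.trusted_available():
            cutoff = target_model.cutoffs.trusted[0]
        elif tc is not None:
            cutoff = tc
        else:
            raise ValueError(
                f"model {_name(target_model.name)} has no trusted cutoff; "
                "supply bit_threshold"
            )
    comp_bits: dict[str, float] = {}
    for model in competitor_models:
        for hit in hmm_search(proteome, model, max_evalue=max_evalue):
            comp_bits[hit.protein_id] = max(
                comp_bits.get(hit.protein_id, -math.inf), hit.bits
            )
    family_id = _name(target_model.name)
    best: Optional[float] = None
    for hit in target_hits:
        if hit.bits < cutoff:
            continue
        if hit.bits <= comp_bits.get(hit.protein_id, -math.inf):
            continue  # matches the competing family better: ignored
        if best is None or hit.bits > best:
            best = hit.bits
    return PresenceCall(
        genome_id=genome_id, family_id=family_id, present=best is not None,
        best_bits=best,
    )


def trait_association(
    presence: Mapping[str, bool], trait: Mapping[str, bool]
) -> tuple[ContingencyTable2x2, OddsRatioResult, tuple[int, int]]:
    """Cross-tabulate family presence against a genome trait.

    Row 1 of the table is the trait-positive group (family present /
    absent), row 2 the trait-negative group. Returns the table, the Fisher
    result, and the two prevalences as integer percentages (trait-positive
    first).
    """
    if set(presence) != set(trait):
        raise ValueError("presence and trait must cover the same genomes")
    a = sum(1 for g in presence if trait[g] and presence[g])
    b = sum(1 for g in presence if trait[g] and not presence[g])
    c = sum(1 for g in presence if not trait[g] and presence[g])
    d = sum(1 for g in presence if not trait[g] and not presence[g])
    table = ContingencyTable2x2(a, b, c, d)
    result = fisher_exact_2x2(table)
    prevalences = (
        round(100 * a / (a + b)) if a + b else 0,
        round(100 * c / (c + d)) if c + d else 0,
    )
    return table, result, prevalences


def loo_threshold_accuracy(
    db: Iterable[CuratedProtein],
    identity_bins: Sequence[tuple[float, float]] = ((0.4, 0.5), (0.5, 0.6), (0.6, 0.8), (0.8, 1.01)),
    step_kinds: Mapping[str, str] | None = None,
    *,
    min_identity: float = 0.40,
    min_coverage: float = 0.80,
    max_evalue: float = 0.01,
) -> pd.DataFrame:
    """Leave-one-out benchmark of the high-confidence thresholds.

    Every characterized protein with at least one step association is
    compared against all other characterized proteins; when its best hit
    (by bit score) reaches ``min_identity`` and ``min_coverage`` of the
    subject, the protein enters the denominator and counts as correct when
    the best hit shares at least one step. Accuracy is reported overall and
    per best-hit identity bin (bins are [lo, hi) fractions), split by step
    kind when ``step_kinds`` maps step ids to "enzyme"/"transporter".

    Returns a DataFrame with columns kind, bin, n, n_correct, accuracy.
    """
    prots = sorted(db, key=lambda p: p.protein_id)
    evaluated = [p for p in prots if p.step_ids]
    db_letters = sum(len(p.sequence) for p in prots) or 1

    def kind_of(p: CuratedProtein) -> str:
        if not step_kinds:
            return "all"
        kinds = {step_kinds.get(s, "enzyme") for s in p.step_ids}
        return kinds.pop() if len(kinds) == 1 else "mixed"

    records = []
    for p in evaluated:
        best = None
        for q in prots:
            if q.protein_id == p.protein_id:
                continue
            aln = align_pair(
                p.sequence, q.sequence,
                query_id=p.protein_id, subject_id=q.protein_id,
                max_evalue=max_evalue, db_letters=db_letters,
            )
            if aln is None:
                continue
            if best is None or (aln.bits, aln.subject_id) > (best[0].bits, best[0].subject_id):
                best = (aln, q)
        if best is None:
            continue
        aln, q = best
        if aln.identity < min_identity or aln.subject_coverage < min_coverage:
            continue  # no hit above thresholds: excluded from the denominator
        correct = bool(set(p.step_ids) & set(q.step_ids))
        records.append((kind_of(p), aln.identity, correct))

    rows = []
    kinds = sorted({k for k, _, _ in records}) or ["all"]
    for kind in kinds:
        sub = [(i, c) for k, i, c in records if k == kind]
        groups: list[tuple[str, list[bool]]] = [
            ("overall", [c for _, c in sub])
        ]
        for lo, hi in identity_bins:
            groups.append(
                (f"{lo:.2f}-{hi:.2f}", [c for i, c in sub if lo <= i < hi])
            )
        for label, flags in groups:
            n = len(flags)
            n_correct = sum(flags)
            rows.append(
                {
                    "kind": kind,
                    "bin": label,
                    "n": n,
                    "n_correct": n_correct,
                    "accuracy": n_correct / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["kind", "bin", "n", "n_correct", "accuracy"])
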