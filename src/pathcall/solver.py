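"""Best-path selection over a pathway's alternate rules.

Given a confidence class for every step, the tool looks for a path that has
all high-confidence steps, or failing that one with no low-confidence
steps, or failing that the path with the highest total score (each
high-confidence step scores +1, each medium-confidence step -0.1, each
low-confidence step -2). When paths tie — e.g. two all-high paths — the one
with more steps is chosen (a single step may be annotated erroneously; a
full complement of steps rarely is), and remaining ties go to the
alternative written first in the pathway definition.

This is a lexicographic maximization of (category, total score, step count,
definition order), where category is 2 for all-high paths, 1 for low-free
paths, 0 otherwise. Paths are step SETS: a step shared between sub-rules is
scored once.

The solver does not enumerate every path. Each rule is reduced to a small
Pareto front of candidate step-sets, pruned with two rules that are safe
under set-union with any enclosing context:

* drop S when some retained T ⊇ S differs only by high-confidence steps
  (extra high steps can never hurt: category is unchanged, score and step
  count never decrease, in any context);
* drop T when some retained S ⊆ T and every extra step of T is medium or
  low (the extras can only lower category/score; when an enclosing context
  already contains them the two collapse to the same set).

A greedy bottom-up recursion (best alternative per sub-rule in isolation)
is *not* correct here: when sub-rules share steps, a locally worse
alternative can be globally free because a sibling already pays for its
steps. The front keeps such options alive. Equality with brute-force
enumeration is property-tested against :func:`pathcall.rules.enumerate_paths`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .confidence import (
    Candidate,
    Confidence,
    ConfidenceThresholds,
    classify_hmm_evidence,
    classify_sequence_evidence,
    combine_evidence,
    step_confidence,
)
from .curated import CuratedDB
from .rules import CyclicRuleError, PathwayDef

__all__ = ["ScoreConfig", "PathResult", "score_path", "best_path", "annotate_genome"]

MAX_FRONT = 100_000  # safety valve; fronts stay tiny for realistic pathways


@dataclass
class ScoreConfig:
    w_high: float = 1.0
    w_medium: float = -0.1
    w_low: float = -2.0

    def __post_init__(self):
        if not self.w_high > self.w_medium > self.w_low:
            raise ValueError("weights must satisfy w_high > w_medium > w_low")

    def weight(self, conf: Confidence) -> float:
        return (self.w_low, self.w_medium, self.w_high)[int(conf)]


@dataclass
class PathResult:
    """The chosen path for one (genome, compound) pair."""

    compound_id: str
    step_ids: list[str]
    per_step_confidence: dict[str, Confidence]
    category: int  # 2 all-high, 1 low-free, 0 otherwise
    total_score: float
    n_high: int
    n_medium: int
    n_low: int
    chosen_candidates: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def category_name(self) -> str:
        return Confidence(self.category).name


def score_path(
    confs: Sequence[Confidence], cfg: ScoreConfig | None = None
) -> tuple[int, float]:
    """(category, total score) of a path from its step confidences."""
    if not confs:
        raise ValueError("empty path")
    cfg = cfg or ScoreConfig()
    category = int(min(confs))
    total = sum(cfg.weight(c) for c in confs)
    return category, total


def _prune_front(front: list[frozenset[str]], conf: Mapping[str, Confidence]) -> list[frozenset[str]]:
    """Deduplicate and apply the two context-safe dominance rules."""
    uniq: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for s in front:
        if s not in seen:
            seen.add(s)
            uniq.append(s)
    n = len(uniq)
    keep = [True] * n
    for i in range(n):
        if not keep[i]:
            continue
        for j in range(n):
            if i == j or not keep[j] or not keep[i]:
                continue
            small, big = (i, j) if uniq[i] < uniq[j] else (j, i) if uniq[j] < uniq[i] else (None, None)
            if small is None:
                continue
            extras = uniq[big] - uniq[small]
            if all(conf[s] is Confidence.high for s in extras):
                keep[small] = False  # the superset is at least as good anywhere
            elif all(conf[s] is not Confidence.high for s in extras):
                keep[big] = False  # the extras can only hurt
    return [s for s, k in zip(uniq, keep) if k]


def best_path(
    pathway: PathwayDef,
    step_conf: Mapping[str, Confidence],
    cfg: ScoreConfig | None = None,
) -> PathResult:
    """Select the path maximizing (category, score, step count, def. order).

    ``step_conf`` maps step ids to confidences; steps absent from the
    mapping are low-confidence (a step with no candidates still counts
    against a path). The result equals a brute-force maximum over all
    expansions of the entry rule.
    """
    cfg = cfg or ScoreConfig()
    if pathway.entry_rule is None:
        raise ValueError(f"{pathway.compound_id}: no entry rule")
    pathway._check_rule_acyclic()
    conf = {sid: step_conf.get(sid, Confidence.low) for sid in pathway.steps}

    memo: dict[str, list[frozenset[str]]] = {}

    def front(rid: str) -> list[frozenset[str]]:
        if rid in pathway.steps:
            return [frozenset([rid])]
        if rid in memo:
            return memo[rid]
        out: list[frozenset[str]] = []
        for alt in pathway.rules[rid].alternatives:
            partial: list[frozenset[str]] = [frozenset()]
            for req in alt:
                sub = front(req)
                partial = [p | s for p in partial for s in sub]
                partial = _prune_front(partial, conf)
                if len(partial) > MAX_FRONT:
                    raise RuntimeError(
                        f"{pathway.compound_id}: rule {rid} Pareto front exceeds {MAX_FRONT}"
                    )
            out.extend(partial)
        out = _prune_front(out, conf)
        memo[rid] = out
        return out

    def key(s: frozenset[str]) -> tuple[int, float, int]:
        confs = [conf[x] for x in s]
        category, total = score_path(confs, cfg)
        return category, total, len(s)

    candidates = front(pathway.entry_rule)
    best_set, best_key = None, None
    for s in candidates:  # earliest (definition order) wins ties
        k = key(s)
        if best_key is None or k > best_key:
            best_set, best_key = s, k
    assert best_set is not None
    step_ids = [sid for sid in pathway.steps if sid in best_set]
    per_step = {sid: conf[sid] for sid in step_ids}
    counts = {c: sum(1 for v in per_step.values() if v is c) for c in Confidence}
    return PathResult(
        compound_id=pathway.compound_id,
        step_ids=step_ids,
        per_step_confidence=per_step,
        category=best_key[0],
        total_score=best_key[1],
        n_high=counts[Confidence.high],
        n_medium=counts[Confidence.medium],
        n_low=counts[Confidence.low],
    )


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

def annotate_genome(
    proteome: Sequence[tuple[str, str]],
    registry: Mapping[str, PathwayDef],
    db: CuratedDB,
    search_config=None,
    thresholds: ConfidenceThresholds | None = None,
    score_config: ScoreConfig | None = None,
    hmms: Mapping[str, object] | None = None,
    candidates_out: Optional[list[Candidate]] = None,
) -> list[PathResult]:
    """Annotate one proteome against every pathway in the registry.

    For each compound: search candidates for every step, limit them, weigh
    each against other-function proteins, classify, and solve for the best
    path. Results are sorted by (category, total score) descending. When one
    protein is the chosen candidate for two or more steps of a chosen path,
    a warning is attached (the tool permits this; it may indicate a fusion
    protein or an over-merged step definition).

    ``hmms`` maps HMM ids to pyhmmer models; steps whose models are absent
    fall back to sequence evidence alone. Pass ``candidates_out`` to collect
    every considered candidate for reporting.
    """
    from .homology import (
        SearchConfig,
        best_other_function_hit,
        hmm_search,
        limit_candidates,
        search_candidates,
    )

    search_config = search_config or SearchConfig()
    thresholds = thresholds or ConfidenceThresholds()
    score_config = score_config or ScoreConfig()
    seq_by_id = dict(proteome)
    hmm_cache: dict[str, list] = {}

    results: list[PathResult] = []
    for compound_id, pathway in registry.items():
        step_confs: dict[str, Confidence] = {}
        best_protein: dict[str, tuple] = {}
        for sid, step in pathway.steps.items():
            hits = limit_candidates(
                search_candidates(proteome, step, db, search_config), search_config
            )
            per_protein: dict[str, Candidate] = {}
            for hit in hits:
                other = best_other_function_hit(
                    seq_by_id[hit.query_id], db, step, search_config,
                    candidate_id=hit.query_id,
                )
                c = Candidate(
                    protein_id=hit.query_id,
                    step_id=sid,
                    evidence="sequence",
                    best_same_step=hit,
                    best_other_function=other,
                )
                c.confidence = classify_sequence_evidence(hit, other, thresholds)
                per_protein[hit.query_id] = c
            for hmm_id in step.hmm_ids:
                model = (hmms or {}).get(hmm_id)
                if model is None:
                    continue  # degrade gracefully to sequence evidence
                if hmm_id not in hmm_cache:
                    hmm_cache[hmm_id] = hmm_search(
                        proteome, model, max_evalue=search_config.max_evalue
                    )
                for hhit in hmm_cache[hmm_id]:
                    c = per_protein.get(hhit.protein_id)
                    if c is None:
                        other = best_other_function_hit(
                            seq_by_id[hhit.protein_id], db, step, search_config,
                            candidate_id=hhit.protein_id,
                        )
                        c = Candidate(
                            protein_id=hhit.protein_id,
                            step_id=sid,
                            evidence="hmm",
                            best_hmm=hhit,
                            best_other_function=other,
                        )
                        c.confidence = classify_hmm_evidence(
                            hhit, other, thresholds
                        )
                        per_protein[hhit.protein_id] = c
                    elif c.best_hmm is None or hhit.bits > c.best_hmm.bits:
                        c.best_hmm = hhit
                        c.evidence = "both"
                        seq_conf = classify_sequence_evidence(
                            c.best_same_step, c.best_other_function, thresholds
                        )
                        hmm_conf = classify_hmm_evidence(
                            hhit, c.best_other_function, thresholds
                        )
                        c.confidence = combine_evidence(seq_conf, hmm_conf)
            cands = list(per_protein.values())
            if candidates_out is not None:
                candidates_out.extend(cands)
            step_confs[sid] = step_confidence(cands)
            ranked = sorted(
                cands,
                key=lambda c: (
                    int(c.confidence),
                    c.best_same_step.bits if c.best_same_step else
                    (c.best_hmm.bits if c.best_hmm else float("-inf")),
                ),
                reverse=True,
            )
            if ranked:
                best_protein[sid] = ranked[0].protein_id

        result = best_path(pathway, step_confs, score_config)
        for sid in result.step_ids:
            if sid in best_protein:
                result.chosen_candidates[sid] = best_protein[sid]
        usage: dict[str, list[str]] = {}
        for sid, pid in result.chosen_candidates.items():
            usage.setdefault(pid, []).append(sid)
        for pid, sids in sorted(usage.items()):
            if len(sids) > 1:
                result.warnings.append(
                    f"protein {pid} is the chosen candidate for steps: "
                    + ", ".join(sorted(sids))
                )
        results.append(result)
    results.sort(key=lambda r: (-r.category, -r.total_score, r.compound_id))
    return results
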