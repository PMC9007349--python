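"""Sequence and profile-HMM homology searches behind a fixed contract.

The annotation rules downstream depend on four alignment quantities:
percent identity, coverage of each sequence, bit score, and E-value. The
bundled engine is Smith-Waterman local alignment (BLOSUM62, gap open 11 /
extend 1) with Karlin-Altschul statistics using the standard gapped
parameters for that scoring system, so the identity/coverage thresholds
behave as they do in the BLAST-family tools they were tuned with. The engine
is pluggable: anything returning :class:`Alignment` objects honouring the
same definitions can be substituted.

Definitions used everywhere in this package:

* identity = identical columns / aligned columns, gap columns included;
* coverage of a sequence = aligned span / sequence length, per sequence;
* "coverage" unqualified in the confidence rules means coverage of the
  characterized (subject) protein.

Profile-HMM search runs through HMMER (via pyhmmer); model coverage is the
fraction of match states spanned by the best-scoring domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import pyhmmer
from Bio import Align
from Bio.Align import substitution_matrices

from .curated import CuratedProtein
from .rules import StepDef

__all__ = [
    "Alignment",
    "HmmHit",
    "SearchConfig",
    "align_pair",
    "search_candidates",
    "limit_candidates",
    "best_other_function_hit",
    "hmm_search",
    "load_hmms",
]

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1,
# as distributed with NCBI BLAST.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class Alignment:
    """One local alignment with the statistics the confidence rules consume."""

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    subject_coverage: float
    bits: float
    evalue: float

    def __post_init__(self):
        for name in ("identity", "query_coverage", "subject_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if not math.isfinite(self.bits):
            raise ValueError("non-finite bit score")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class HmmHit:
    """A protein-vs-profile-HMM hit; coverage is measured on the model."""

    protein_id: str
    hmm_id: str
    model_coverage: float
    bits: float
    evalue: float
    trusted_cutoff: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.model_coverage <= 1.0:
            raise ValueError(f"model_coverage out of [0,1]: {self.model_coverage}")


@dataclass
class SearchConfig:
    """Candidate-search knobs.

    Searches are run with a relatively lax E-value threshold (0.01); the
    identity/coverage constraints downstream do the real filtering. Per step
    only the four top candidates by bit score are kept, at most two of which
    may align below 40% identity; when weighing a candidate against proteins
    with other functions, only its top eight characterized hits are examined.
    """

    max_evalue: float = 0.01
    max_candidates_per_step: int = 4
    max_low_identity_candidates: int = 2
    low_identity_threshold: float = 0.40
    max_characterized_hits: int = 8

    def __post_init__(self):
        if self.max_evalue <= 0 or self.low_identity_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if min(self.max_candidates_per_step, self.max_low_identity_candidates,
               self.max_characterized_hits) <= 0:
            raise ValueError("candidate limits must be positive")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def raw_to_bits(raw_score: float) -> float:
    """Convert a raw Smith-Waterman score to a bit score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def bits_to_evalue(bits: float, query_len: int, db_letters: int) -> float:
    """Expected chance hits at this score searching ``db_letters`` residues."""
    return query_len * db_letters * 2.0 ** (-bits)


def _alignment_stats(aln) -> tuple[float, float, float]:
    """(identity, coverage_of_target, coverage_of_query) for a Bio alignment."""
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    t_blocks, q_blocks = aln.aligned  # target rows, query rows of coordinates
    t_span = t_blocks[-1][1] - t_blocks[0][0]
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    cov_t = t_span / len(aln.target)
    cov_q = q_span / len(aln.query)
    return identity, cov_t, cov_q


def align_pair(
    a: str,
    b: str,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    max_evalue: float | None = 0.01,
    db_letters: int | None = None,
) -> Alignment | None:
    """Best local alignment of two protein sequences, or None below threshold.

    ``db_letters`` sets the database size for E-value normalization; it
    defaults to the subject length (single-sequence search). Identity is
    symmetric: align_pair(a, b) and align_pair(b, a) report the same identity
    (the dynamic program is run on a canonical orientation of the pair).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    # canonical orientation so tie-broken tracebacks cannot differ between
    # (a,b) and (b,a)
    swapped = (len(b), b) < (len(a), a)
    target, query = (b, a) if swapped else (a, b)
    aligner = _aligner()
    score = aligner.score(target, query)
    bits = raw_to_bits(score)
    n = db_letters if db_letters is not None else len(b)
    evalue = bits_to_evalue(bits, len(a), n)
    if max_evalue is not None and evalue > max_evalue:
        return None
    aln = aligner.align(target, query)[0]
    identity, cov_t, cov_q = _alignment_stats(aln)
    cov_a, cov_b = (cov_q, cov_t) if swapped else (cov_t, cov_q)
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        identity=identity,
        query_coverage=cov_a,
        subject_coverage=cov_b,
        bits=bits,
        evalue=evalue,
    )


def _db_letters(db: Iterable[CuratedProtein]) -> int:
    return sum(len(p.sequence) for p in db)


def search_candidates(
    proteome: Sequence[tuple[str, str]],
    step: StepDef,
    db: dict[str, CuratedProtein],
    config: SearchConfig | None = None,
) -> list[Alignment]:
    """Align every proteome protein against the step's characterized proteins.

    Each proteome protein is represented by its best-scoring alignment to any
    of the step's proteins (E <= config.max_evalue). Result sorted by bits
    descending, ties by (subject_id, query_id).
    """
    config = config or SearchConfig()
    missing = [cid for cid in step.curated_ids if cid not in db]
    if missing:
        raise KeyError(f"step {step.step_id}: curated ids not in database: {missing}")
    db_letters = _db_letters(db.values()) or 1
    hits: list[Alignment] = []
    for pid, seq in proteome:
        best: Alignment | None = None
        for cid in step.curated_ids:
            aln = align_pair(
                seq,
                db[cid].sequence,
                query_id=pid,
                subject_id=cid,
                max_evalue=config.max_evalue,
                db_letters=db_letters,
            )
            if aln is None:
                continue
            if best is None or (aln.bits, aln.subject_id) > (best.bits, best.subject_id):
                best = aln
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (-h.bits, h.subject_id, h.query_id))
    return hits


def limit_candidates(
    hits: Sequence[Alignment], config: SearchConfig | None = None
) -> list[Alignment]:
    """Keep the top candidates by bit score, capping low-identity ones.

    At most ``max_candidates_per_step`` hits are kept; among them at most
    ``max_low_identity_candidates`` may align below the identity threshold.
    When a low-identity hit is displaced, the next higher-identity hit down
    the bit-score order back-fills its slot.
    """
    config = config or SearchConfig()
    ordered = sorted(hits, key=lambda h: (-h.bits, h.subject_id, h.query_id))
    kept: list[Alignment] = []
    n_low = 0
    for hit in ordered:
        if len(kept) >= config.max_candidates_per_step:
            break
        low = hit.identity < config.low_identity_threshold
        if low and n_low >= config.max_low_identity_candidates:
            continue
        kept.append(hit)
        n_low += low
    return kept


def best_other_function_hit(
    candidate_seq: str,
    db: dict[str, CuratedProtein],
    step: StepDef,
    config: SearchConfig | None = None,
    *,
    candidate_id: str = "candidate",
) -> Alignment | None:
    """Best characterized hit with a function other than this step's.

    Only the candidate's top ``max_characterized_hits`` characterized
    alignments by bit score are examined; among them the best-bits alignment
    to a protein neither associated with the step nor on its ignore list is
    returned (None if all top hits are same-step or ignored).
    """
    config = config or SearchConfig()
    db_letters = _db_letters(db.values()) or 1
    alns: list[Alignment] = []
    for cid, prot in db.items():
        aln = align_pair(
            candidate_seq,
            prot.sequence,
            query_id=candidate_id,
            subject_id=cid,
            max_evalue=config.max_evalue,
            db_letters=db_letters,
        )
        if aln is not None:
            alns.append(aln)
    alns.sort(key=lambda h: (-h.bits, h.subject_id))
    same_step = set(step.curated_ids)
    ignored = set(step.ignore_ids)
    for aln in alns[: config.max_characterized_hits]:
        cid = aln.subject_id
        if cid in same_step or cid in ignored:
            continue
        if step.step_id in db[cid].step_ids:
            continue
        return aln
    return None


# ---------------------------------------------------------------------------
# profile HMMs
# ---------------------------------------------------------------------------

def _name(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def load_hmms(path: str) -> dict[str, pyhmmer.plan7.HMM]:
    """Read all models from an HMMER3 text file, keyed by model name."""
    models: dict[str, pyhmmer.plan7.HMM] = {}
    with pyhmmer.plan7.HMMFile(path) as fh:
        for hmm in fh:
            models[_name(hmm.name)] = hmm
    return models


def hmm_search(
    proteome: Sequence[tuple[str, str]],
    hmm: pyhmmer.plan7.HMM,
    *,
    max_evalue: float = 0.01,
) -> list[HmmHit]:
    """Search a proteome with one profile HMM.

    Model coverage is the span of the best-scoring domain over the model's
    match states divided by the model length. The model's trusted cutoff
    (sequence bit score) is attached when the model defines one.
    """
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(name=pid.encode(), sequence=seq).digitize(alphabet)
        for pid, seq in proteome
    ]
    if not seqs:
        return []
    pipeline = pyhmmer.plan7.Pipeline(alphabet, E=max_evalue)
    top_hits = pipeline.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(alphabet, seqs))
    trusted = hmm.cutoffs.trusted[0] if hmm.cutoffs.trusted_available() else None
    hmm_id = _name(hmm.name)
    out: list[HmmHit] = []
    for hit in top_hits:
        best_dom = max(hit.domains, key=lambda d: d.score, default=None)
        if best_dom is None:
            continue
        span = best_dom.alignment.hmm_to - best_dom.alignment.hmm_from + 1
        out.append(
            HmmHit(
                protein_id=_name(hit.name),
                hmm_id=hmm_id,
                model_coverage=min(1.0, span / hmm.M),
                bits=hit.score,
                evalue=hit.evalue,
                trusted_cutoff=trusted,
            )
        )
    out.sort(key=lambda h: (-h.bits, h.protein_id))
    return out
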