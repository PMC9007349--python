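import pytest
from hypothesis import given, settings, strategies as st

from pathcall.curated import CuratedDB, CuratedProtein
from pathcall.fixtures import mutate_to_identity, random_protein
from pathcall.homology import (
    Alignment,
    SearchConfig,
    align_pair,
    best_other_function_hit,
    bits_to_evalue,
    hmm_search,
    limit_candidates,
    search_candidates,
)
from pathcall.rules import StepDef
from .conftest import build_hmm


class TestAlignPair:
    def test_self_alignment_is_perfect(self):
        seq = random_protein(200, seed=1)
        aln = align_pair(seq, seq)
        assert aln.identity == 1.0
        assert aln.query_coverage == 1.0
        assert aln.subject_coverage == 1.0

    def test_half_substituted_identity_matches_column_count(self):
        # substitution-only mutant: the column-count oracle is the exact
        # position-wise match fraction of the two equal-length sequences
        a = random_protein(300, seed=2)
        b = mutate_to_identity(a, 0.50, seed=3)
        oracle = sum(x == y for x, y in zip(a, b)) / len(a)
        aln = align_pair(a, b)
        assert aln.identity == pytest.approx(oracle, abs=0.02)

    def test_unrelated_short_sequences_rejected_at_evalue(self):
        # E-values are normalized to the searched database size; 10 kres is
        # a small characterized-protein set
        misses = sum(
            align_pair(
                random_protein(60, seed=2 * i), random_protein(60, seed=2 * i + 1),
                db_letters=10_000,
            )
            is None
            for i in range(100)
        )
        assert misses == 100

    def test_identity_is_symmetric(self):
        for seed in range(5):
            a = random_protein(150, seed=seed)
            b = mutate_to_identity(a, 0.6, seed=seed + 50)[: 120]
            ab = align_pair(a, b)
            ba = align_pair(b, a)
            assert ab.identity == ba.identity
            assert ab.bits == ba.bits
            assert ab.query_coverage == ba.subject_coverage
            assert ab.subject_coverage == ba.query_coverage

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_pair("", "MKVL")

    def test_evalue_monotone_decreasing_in_bits(self):
        evalues = [bits_to_evalue(b, 300, 10_000) for b in (10, 20, 40, 80)]
        assert evalues == sorted(evalues, reverse=True)


def _aln(bits, identity, qid="q", sid="s"):
    return Alignment(
        query_id=qid, subject_id=sid, identity=identity,
        query_coverage=0.9, subject_coverage=0.9, bits=bits, evalue=1e-10,
    )


class TestLimitCandidates:
    def test_top_four_by_bits(self):
        identities = [0.80, 0.70, 0.50, 0.38, 0.35, 0.33]
        hits = [_aln(100 - i, ident, qid=f"q{i}") for i, ident in enumerate(identities)]
        kept = limit_candidates(hits)
        assert [h.identity for h in kept] == [0.80, 0.70, 0.50, 0.38]

    def test_at_most_two_low_identity(self):
        hits = [_aln(100 - i, ident, qid=f"q{i}")
                for i, ident in enumerate([0.39, 0.38, 0.37, 0.36])]
        kept = limit_candidates(hits)
        assert [h.identity for h in kept] == [0.39, 0.38]

    def test_higher_identity_backfills_displaced_low_identity_slot(self):
        hits = [_aln(100 - i, ident, qid=f"q{i}")
                for i, ident in enumerate([0.39, 0.38, 0.37, 0.60, 0.55])]
        kept = limit_candidates(hits)
        assert [h.identity for h in kept] == [0.39, 0.38, 0.60, 0.55]

    def test_empty_input(self):
        assert limit_candidates([]) == []

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.floats(1, 500, allow_nan=False),
                st.floats(0.1, 1.0, allow_nan=False),
            ),
            max_size=12,
        )
    )
    def test_limits_hold_for_any_input(self, pairs):
        hits = [_aln(b, i, qid=f"q{n}") for n, (b, i) in enumerate(pairs)]
        kept = limit_candidates(hits)
        assert len(kept) <= 4
        assert sum(h.identity < 0.40 for h in kept) <= 2
        bit_order = [h.bits for h in kept]
        assert bit_order == sorted(bit_order, reverse=True)
        assert all(h in hits for h in kept)


def _db(entries):
    db = CuratedDB()
    for pid, seq, steps in entries:
        db[pid] = CuratedProtein(pid, seq, step_ids=list(steps))
    return db


class TestSearchCandidates:
    def setup_method(self):
        self.exemplar = random_protein(250, seed=10)
        self.db = _db([("cur1", self.exemplar, ["glk"])])
        self.step = StepDef("glk", curated_ids=["cur1"])

    def test_exact_copy_is_top_hit(self):
        proteome = [("g1", self.exemplar), ("g2", random_protein(250, seed=11))]
        hits = search_candidates(proteome, self.step, self.db)
        assert hits[0].query_id == "g1"
        assert hits[0].identity == 1.0

    def test_no_homolog_empty(self):
        proteome = [("g1", random_protein(250, seed=12))]
        assert search_candidates(proteome, self.step, self.db) == []

    def test_paralogs_ordered_by_bits(self):
        proteome = [
            ("weak", mutate_to_identity(self.exemplar, 0.45, seed=13)),
            ("strong", mutate_to_identity(self.exemplar, 0.90, seed=14)),
        ]
        hits = search_candidates(proteome, self.step, self.db)
        assert [h.query_id for h in hits] == ["strong", "weak"]
        assert hits[0].bits > hits[1].bits


class TestBestOtherFunctionHit:
    def test_all_top_hits_same_step_gives_none(self):
        base = random_protein(250, seed=20)
        entries = [(f"same{i}", mutate_to_identity(base, 0.90, seed=21 + i), ["glk"])
                   for i in range(3)]
        db = _db(entries)
        step = StepDef("glk", curated_ids=[pid for pid, _, _ in entries])
        assert best_other_function_hit(base, db, step) is None

    def test_ignored_paralog_skipped_for_next_other_function(self):
        base = random_protein(250, seed=30)
        db = _db([
            ("same", mutate_to_identity(base, 0.80, seed=31), ["glk"]),
            ("ignored", mutate_to_identity(base, 0.98, seed=32), []),
            ("otherfn", mutate_to_identity(base, 0.90, seed=33), ["other_step"]),
        ])
        step = StepDef("glk", curated_ids=["same"], ignore_ids=["ignored"])
        hit = best_other_function_hit(base, db, step)
        assert hit.subject_id == "otherfn"

    def test_other_function_outranked_beyond_top_eight(self):
        base = random_protein(250, seed=40)
        entries = [(f"same{i}", mutate_to_identity(base, 0.90, seed=41 + i), ["glk"])
                   for i in range(8)]
        entries.append(("otherfn", mutate_to_identity(base, 0.55, seed=60), ["other"]))
        db = _db(entries)
        step = StepDef("glk", curated_ids=[f"same{i}" for i in range(8)])
        assert best_other_function_hit(base, db, step) is None
        # with a window of nine the other-function hit becomes visible
        cfg = SearchConfig(max_characterized_hits=9)
        assert best_other_function_hit(base, db, step, cfg).subject_id == "otherfn"


class TestHmmSearch:
    def test_consensus_covers_the_model(self):
        hmm = build_hmm(7)
        consensus = hmm.consensus.upper()
        hits = hmm_search([("cons", consensus)], hmm)
        assert hits and hits[0].model_coverage >= 0.95

    def test_random_protein_not_reported(self):
        hmm = build_hmm(7)
        assert hmm_search([("rand", random_protein(120, seed=99))], hmm) == []

    def test_truncated_consensus_covers_truncated_fraction(self):
        hmm = build_hmm(7)
        consensus = hmm.consensus.upper()
        truncated = consensus[: int(len(consensus) * 0.6)]
        hits = hmm_search([("trunc", truncated)], hmm)
        assert hits[0].model_coverage == pytest.approx(0.60, abs=0.05)
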