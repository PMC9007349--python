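import math
from math import comb

import numpy as np
import pytest

from pathcall.assoc import (
    ContingencyTable2x2,
    family_presence,
    fisher_exact_2x2,
    loo_threshold_accuracy,
    trait_association,
)
from pathcall.curated import CuratedProtein
from pathcall.fixtures import mutate_to_identity, random_protein
from .conftest import build_hmm


def fisher_p_enumeration(a, b, c, d):
    """Independent oracle: exact two-sided p by full enumeration of all
    tables with the observed margins (sum of probabilities <= observed)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-10)
    )


class TestFisher:
    def test_family_depletion_table(self):
        # 22 of 232 comparison genomes carry the family vs 7 of 15 in the
        # group of interest: strong depletion
        res = fisher_exact_2x2(ContingencyTable2x2(22, 210, 7, 8))
        assert res.odds_ratio == pytest.approx(0.12, abs=0.005)
        assert res.p_two_sided == pytest.approx(0.0005, abs=0.0001)

    def test_symmetric_table_is_null(self):
        res = fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1))
        assert res.odds_ratio == 1.0
        assert res.p_two_sided == 1.0

    def test_row_swap_inverts_odds_ratio(self):
        res = fisher_exact_2x2(ContingencyTable2x2(7, 8, 22, 210))
        assert res.odds_ratio == pytest.approx(8.35, abs=0.01)

    def test_p_matches_full_enumeration(self):
        rng = np.random.default_rng(99)
        tables = [(22, 210, 7, 8), (12, 5, 7, 9), (1, 9, 11, 3)]
        for _ in range(100):
            a, b, c, d = rng.integers(0, 60, size=4)
            if a + b and c + d and a + c and b + d:
                tables.append((int(a), int(b), int(c), int(d)))
        for a, b, c, d in tables:
            res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert res.p_two_sided == pytest.approx(
                fisher_p_enumeration(a, b, c, d), rel=1e-6, abs=1e-12
            )

    def test_row_swap_reciprocity_property(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 40, size=4))
            t = ContingencyTable2x2(a, b, c, d)
            r, rs = fisher_exact_2x2(t), fisher_exact_2x2(t.row_swapped())
            assert rs.odds_ratio == pytest.approx(1.0 / r.odds_ratio)
            assert rs.p_two_sided == pytest.approx(r.p_two_sided)

    def test_zero_cell_gives_infinite_or_zero_or(self):
        assert math.isinf(fisher_exact_2x2(ContingencyTable2x2(3, 0, 5, 8)).odds_ratio)
        assert fisher_exact_2x2(ContingencyTable2x2(0, 3, 5, 8)).odds_ratio == 0.0

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 8))
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(ContingencyTable2x2(0, 4, 0, 8))


class TestTraitAssociation:
    def test_prevalences_rounded_to_integer_percent(self):
        presence = {f"g{i}": i < 7 for i in range(15)}
        presence |= {f"h{i}": i < 22 for i in range(232)}
        trait = {g: g.startswith("g") for g in presence}
        table, res, prev = trait_association(presence, trait)
        assert (table.a, table.b, table.c, table.d) == (7, 8, 22, 210)
        assert prev == (47, 9)
        assert res.odds_ratio == pytest.approx(8.35, abs=0.01)

    def test_all_genomes_trait_positive_is_degenerate(self):
        presence = {"g1": True, "g2": False}
        trait = {"g1": True, "g2": True}
        with pytest.raises(ValueError, match="margin"):
            trait_association(presence, trait)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same genomes"):
            trait_association({"g1": True}, {"g2": True})

    def test_independent_presence_gives_null_odds_ratio(self):
        rng = np.random.default_rng(2024)
        inside = 0
        for _ in range(40):
            pres = rng.random(400) < 0.5
            trait = rng.random(400) < 0.5
            _, res, _ = trait_association(
                {f"g{i}": bool(pres[i]) for i in range(400)},
                {f"g{i}": bool(trait[i]) for i in range(400)},
            )
            inside += 0.6 <= res.odds_ratio <= 1.7
        assert inside >= 36  # ~95% of seeds


class TestFamilyPresence:
    def test_present_above_cutoff_beats_competitor(self):
        target = build_hmm(7, name=b"target")
        competitor = build_hmm(8, name=b"competitor")
        proteome = [("member", target.consensus.upper())]
        call = family_presence(proteome, target, [competitor], bit_threshold=25.0)
        assert call.present and call.best_bits > 25.0

    def test_competitor_dominated_protein_ignored(self):
        target = build_hmm(7, name=b"target")
        competitor = build_hmm(8, name=b"competitor")
        proteome = [("confusable", competitor.consensus.upper())]
        call = family_presence(proteome, target, [competitor], bit_threshold=5.0)
        assert not call.present

    def test_below_cutoff_absent(self):
        target = build_hmm(7, name=b"target")
        proteome = [("member", target.consensus.upper())]
        call = family_presence(proteome, target, bit_threshold=1e6)
        assert not call.present and call.best_bits is None

    def test_missing_cutoff_without_override_errors(self):
        target = build_hmm(7, name=b"target")
        with pytest.raises(ValueError, match="trusted cutoff"):
            family_presence([("x", target.consensus.upper())], target)


def _loo_db():
    prots = []
    # five two-member same-step families at ~80% identity
    for i in range(5):
        base = random_protein(300, seed=100 + i)
        prots.append(CuratedProtein(f"famA{i}", base, step_ids=[f"st{i}"]))
        prots.append(
            CuratedProtein(
                f"famB{i}", mutate_to_identity(base, 0.80, seed=200 + i),
                step_ids=[f"st{i}"],
            )
        )
    # cross-step decoy pairs whose nearest neighbors sit at ~45% identity
    for j in range(3):
        base = random_protein(300, seed=300 + j)
        prots.append(CuratedProtein(f"decA{j}", base, step_ids=[f"dA{j}"]))
        prots.append(
            CuratedProtein(
                f"decB{j}", mutate_to_identity(base, 0.45, seed=400 + j),
                step_ids=[f"dB{j}"],
            )
        )
    # a singleton with no hit above the thresholds: excluded from the denominator
    prots.append(CuratedProtein("lone", random_protein(300, seed=999), step_ids=["stx"]))
    return prots


class TestLooBenchmark:
    def test_planted_families_and_decoys(self):
        report = loo_threshold_accuracy(_loo_db())
        by_bin = {row["bin"]: row for _, row in report.iterrows()}
        assert by_bin["overall"]["n"] == 16  # 10 family + 6 decoy, singleton excluded
        assert by_bin["0.40-0.50"]["accuracy"] == 0.0
        assert by_bin["0.40-0.50"]["n"] == 6
        high_bins = [by_bin["0.60-0.80"], by_bin["0.80-1.01"]]
        assert sum(r["n"] for r in high_bins) == 10
        assert all(r["accuracy"] == 1.0 for r in high_bins if r["n"])

    def test_kind_split(self):
        kinds = {f"st{i}": "enzyme" for i in range(5)}
        kinds |= {f"dA{j}": "transporter" for j in range(3)}
        kinds |= {f"dB{j}": "transporter" for j in range(3)}
        kinds["stx"] = "enzyme"
        report = loo_threshold_accuracy(_loo_db(), step_kinds=kinds)
        enz = report[(report["kind"] == "enzyme") & (report["bin"] == "overall")]
        tra = report[(report["kind"] == "transporter") & (report["bin"] == "overall")]
        assert enz.iloc[0]["accuracy"] == 1.0
        assert tra.iloc[0]["accuracy"] == 0.0
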