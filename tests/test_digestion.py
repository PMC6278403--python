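import io
import math
import random

import pytest

from biopepsim.digestion import (CleavageRule, Protease, SiteClause,
                                 builtin_rulebook, cut_sites, digest,
                                 get_protease, load_rulebook, rank_proteases,
                                 search_active_fragments)
from biopepsim.reference_db import BioactivePeptide, ReferenceSet
from biopepsim.sequence_io import ProteinRecord

from conftest import random_protein

REQUIRED_ENZYMES = [
    "trypsin", "chymotrypsin A", "chymotrypsin C", "pepsin (pH > 2)",
    "papain", "bromelain", "ficin", "thermolysin", "proteinase K",
    "pancreatic elastase",
]


def oracle_cut_sites(sequence: str, protease: Protease) -> list[int]:
    """Independent per-bond window evaluator."""
    offsets = {"p2": -2, "p1": -1, "p1prime": 0, "p2prime": 1}

    def clause_matches(clause: SiteClause, bond: int) -> bool:
        for pos, off in offsets.items():
            allowed = getattr(clause, pos)
            if allowed is None:
                continue
            idx = bond + off
            if not (0 <= idx < len(sequence)) or sequence[idx] not in allowed:
                return False
        return True

    sites = []
    for bond in range(1, len(sequence)):
        if any(clause_matches(c, bond) for c in protease.rule.clauses) and \
           not any(clause_matches(e, bond) for e in protease.rule.exceptions):
            sites.append(bond)
    return sites


class TestCutSites:
    def test_trypsin_akrpstk(self):
        trypsin = get_protease("trypsin")
        protein = ProteinRecord(id="p", sequence="AKRPSTK")
        # after K2 only: R3 is followed by P (veto); K7 is C-terminal (no bond)
        assert cut_sites(protein, trypsin) == [2]

    def test_single_residue_protein_has_no_bonds(self):
        for protease in builtin_rulebook():
            assert cut_sites(ProteinRecord(id="p", sequence="K"), protease) == []

    def test_exceptions_only_remove_sites(self, rng):
        base = Protease(name="noexc", rule=CleavageRule(
            clauses=(SiteClause(p1=frozenset("KR")),)))
        vetoed = Protease(name="exc", rule=CleavageRule(
            clauses=(SiteClause(p1=frozenset("KR")),),
            exceptions=(SiteClause(p1prime=frozenset("P")),)))
        for _ in range(20):
            protein = random_protein(rng, 60)
            assert set(cut_sites(protein, vetoed)) <= set(cut_sites(protein, base))

    def test_matches_brute_force_oracle_all_bundled_rules(self, rng):
        rulebook = builtin_rulebook()
        for _ in range(30):
            protein = random_protein(rng, rng.randint(5, 120))
            for protease in rulebook:
                assert cut_sites(protein, protease) == \
                    oracle_cut_sites(protein.sequence, protease)

    def test_required_enzymes_present(self):
        names = {p.name for p in builtin_rulebook()}
        for name in REQUIRED_ENZYMES:
            assert name in names


class TestDigest:
    def test_no_sites_single_fragment(self):
        trypsin = get_protease("trypsin")
        protein = ProteinRecord(id="p", sequence="ACDEAG")
        result = digest(protein, [trypsin])
        assert [f.sequence for f in result.fragments] == ["ACDEAG"]

    def test_trypsin_akrpstk_fragments(self):
        trypsin = get_protease("trypsin")
        result = digest(ProteinRecord(id="p", sequence="AKRPSTK"), [trypsin])
        assert [f.sequence for f in result.fragments] == ["AK", "RPSTK"]
        assert [(f.start, f.end) for f in result.fragments] == [(1, 2), (3, 7)]

    def test_too_many_proteases(self):
        book = builtin_rulebook()
        with pytest.raises(ValueError, match="1..3"):
            digest(ProteinRecord(id="p", sequence="ACDE"), book[:4])

    def test_zero_proteases(self):
        with pytest.raises(ValueError):
            digest(ProteinRecord(id="p", sequence="ACDE"), [])

    def test_conservation_property(self, rng):
        rulebook = builtin_rulebook()
        for _ in range(25):
            protein = random_protein(rng, rng.randint(2, 150))
            for protease in rulebook:
                result = digest(protein, [protease])
                assert "".join(f.sequence for f in result.fragments) == protein.sequence

    def test_union_property_pairs(self, rng):
        trypsin = get_protease("trypsin")
        chymo = get_protease("chymotrypsin A")
        for _ in range(20):
            protein = random_protein(rng, rng.randint(10, 120))
            combined = digest(protein, [trypsin, chymo])
            expected = sorted(set(cut_sites(protein, trypsin))
                              | set(cut_sites(protein, chymo)))
            boundaries = [f.end for f in combined.fragments[:-1]]
            assert boundaries == expected

    def test_determinism(self, rng):
        protein = random_protein(rng, 100)
        enzymes = [get_protease("pepsin (pH > 2)")]
        a = digest(protein, enzymes)
        b = digest(protein, enzymes)
        assert a.fragments == b.fragments

    def test_missed_cleavage_counts(self, rng):
        trypsin = get_protease("trypsin")
        for m in (1, 2):
            for _ in range(10):
                protein = random_protein(rng, 80)
                result = digest(protein, [trypsin], missed_cleavages=m)
                s = len(result.fragments) - 1  # cut sites
                expected = sum(max(0, s + 1 - span + 1)
                               for span in range(2, m + 2))
                assert len(result.partial_fragments) == expected
                assert all(f.missed >= 1 for f in result.partial_fragments)

    def test_missed_cleavage_sequences(self):
        trypsin = get_protease("trypsin")
        protein = ProteinRecord(id="p", sequence="AKGKDD")
        result = digest(protein, [trypsin], missed_cleavages=1)
        assert [f.sequence for f in result.fragments] == ["AK", "GK", "DD"]
        assert [f.sequence for f in result.partial_fragments] == ["AKGK", "GKDD"]


class TestSearchActiveFragments:
    def test_whole_fragment_match(self, tiny_refset):
        trypsin = get_protease("trypsin")
        refset = ReferenceSet(
            entries=[BioactivePeptide(sequence="AK", activity="ACE inhibitor")],
            version_tag="t")
        result = search_active_fragments(
            digest(ProteinRecord(id="p", sequence="AKRPSTK"), [trypsin]), refset)
        assert result.match_count("ACE inhibitor") == 1

    def test_substring_is_not_a_match(self):
        refset = ReferenceSet(
            entries=[BioactivePeptide(sequence="AK", activity="ACE inhibitor")],
            version_tag="t")
        protein = ProteinRecord(id="p", sequence="GAKDD")  # digest leaves GAK... intact
        trypsin = get_protease("trypsin")
        result = search_active_fragments(digest(protein, [trypsin]), refset)
        # fragments are GAK, DD; neither equals AK exactly
        assert result.match_count("ACE inhibitor") == 0

    def test_multi_activity_fragment_counts_per_activity(self, tiny_refset):
        # chymotrypsin A cuts after W2, leaving KF intact at the C-terminus
        chymo = get_protease("chymotrypsin A")
        protein = ProteinRecord(id="p", sequence="DWKF")
        result = search_active_fragments(digest(protein, [chymo]), tiny_refset)
        assert [f.sequence for f in result.fragments] == ["DW", "KF"]
        assert result.match_count("DPP-IV inhibitor") == 1
        assert result.match_count("antihypertensive") == 1

    def test_empty_refset_usage_error(self):
        trypsin = get_protease("trypsin")
        result = digest(ProteinRecord(id="p", sequence="AKDD"), [trypsin])
        with pytest.raises(ValueError, match="empty"):
            search_active_fragments(result, ReferenceSet(entries=[], version_tag="x"))

    def test_planted_cleavage_release_count(self):
        # engineer a protein where trypsin releases 5 copies of reference "GR"
        trypsin = get_protease("trypsin")
        protein = ProteinRecord(id="p", sequence="GR" * 5 + "DDD")
        refset = ReferenceSet(
            entries=[BioactivePeptide(sequence="GR", activity="ACE inhibitor")],
            version_tag="t")
        result = search_active_fragments(digest(protein, [trypsin]), refset)
        assert result.match_count("ACE inhibitor") == 5


class TestRankProteases:
    def test_single_protease_single_row(self, tiny_refset):
        chymo = get_protease("chymotrypsin A")
        rows = rank_proteases(ProteinRecord(id="p", sequence="DWKF"),
                              [chymo], tiny_refset, "DPP-IV inhibitor")
        assert len(rows) == 1
        assert rows[0]["protease"] == "chymotrypsin A"
        assert rows[0]["DPP-IV inhibitor"] == 1

    def test_sorted_descending_with_name_tiebreak(self, rng, tiny_refset):
        rows = rank_proteases(random_protein(rng, 200), builtin_rulebook(),
                              tiny_refset, "DPP-IV inhibitor")
        counts = [r["DPP-IV inhibitor"] for r in rows]
        assert counts == sorted(counts, reverse=True)
        for a, b in zip(rows, rows[1:]):
            if a["DPP-IV inhibitor"] == b["DPP-IV inhibitor"]:
                assert str(a["protease"]) < str(b["protease"])

    def test_more_cuts_can_release_fewer_matches(self):
        # cutter A releases the tripeptide IPP intact; the finer cutter B
        # additionally cuts inside it, destroying the match
        coarse = Protease(name="coarse", rule=CleavageRule(
            clauses=(SiteClause(p1=frozenset("D")),
                     SiteClause(p1prime=frozenset("D")))))
        fine = Protease(name="fine", rule=CleavageRule(
            clauses=(SiteClause(p1=frozenset("D")),
                     SiteClause(p1prime=frozenset("D")),
                     SiteClause(p1=frozenset("I")))))
        protein = ProteinRecord(id="p", sequence="GGDIPPDGG")
        refset = ReferenceSet(
            entries=[BioactivePeptide(sequence="IPP", activity="ACE inhibitor")],
            version_tag="t")
        n_coarse = search_active_fragments(digest(protein, [coarse]), refset) \
            .match_count("ACE inhibitor")
        n_fine = search_active_fragments(digest(protein, [fine]), refset) \
            .match_count("ACE inhibitor")
        assert len(cut_sites(protein, fine)) > len(cut_sites(protein, coarse))
        assert n_fine < n_coarse
        rows = rank_proteases(protein, [coarse, fine], refset, "ACE inhibitor")
        assert [r["protease"] for r in rows] == ["coarse", "fine"]

    def test_unknown_activity(self, rng, tiny_refset):
        with pytest.raises(ValueError, match="unknown activity"):
            rank_proteases(random_protein(rng, 50), builtin_rulebook(),
                           tiny_refset, "no such activity")

    def test_empty_rulebook(self, rng, tiny_refset):
        with pytest.raises(ValueError, match="rulebook"):
            rank_proteases(random_protein(rng, 50), [], tiny_refset, "ACE inhibitor")

    def test_combinations_added(self, tiny_refset):
        protein = ProteinRecord(id="p", sequence="DRKFGPAY")
        book = [get_protease("trypsin"), get_protease("chymotrypsin A")]
        rows = rank_proteases(protein, book, tiny_refset, "DPP-IV inhibitor",
                              combinations=[["trypsin", "chymotrypsin A"]])
        assert len(rows) == 3
        assert any(r["protease"] == "trypsin + chymotrypsin A" for r in rows)


class TestRulebookIO:
    def test_load_custom_rulebook(self):
        text = """
- name: cut-after-K
  ec: "-"
  clauses:
    - p1: [K]
"""
        book = load_rulebook(io.StringIO(text))
        assert book[0].name == "cut-after-K"
        assert book[0].ec_number == "-"
        assert cut_sites(ProteinRecord(id="p", sequence="AKPA"), book[0]) == [2]

    def test_duplicate_names_rejected(self):
        text = "- name: x\n  clauses: [{p1: [K]}]\n- name: x\n  clauses: [{p1: [R]}]\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_rulebook(io.StringIO(text))

    def test_empty_clause_list_rejected(self):
        with pytest.raises(ValueError):
            CleavageRule(clauses=())

    def test_invalid_residue_in_clause(self):
        with pytest.raises(ValueError, match="invalid residues"):
            SiteClause(p1=frozenset("K1"))

    def test_get_protease_unknown(self):
        with pytest.raises(KeyError):
            get_protease("no-such-enzyme")
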