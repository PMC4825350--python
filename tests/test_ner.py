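"""Dictionary matching, spelling tolerance, composites, chemical variants."""

import random
import re

import pytest

from cidminer.lexicon import Lexicon, LexiconEntry, normalize_key
from cidminer.ner import (
    MatchConfig,
    Mention,
    detect_composites,
    find_mentions,
    normalize_chemical,
    prefer_drug_induced,
    spell_tolerant_lookup,
)

NO_SPELL = MatchConfig(spelling_max_edits=0)


def lex_of(*pairs, entity_class="disease"):
    lex = Lexicon()
    for surface, cid in pairs:
        lex.add(LexiconEntry(surface, cid, entity_class))
    return lex


def brute_force_mentions(text, lexicon, entity_class="disease"):
    """Oracle: try every dictionary term at every boundary pair; keep
    leftmost-longest greedily."""
    n = len(text)
    alnum = [c.isalnum() and c.isascii() for c in text]
    starts = [i for i in range(n) if alnum[i] and (i == 0 or not alnum[i - 1])]
    ends = [j for j in range(1, n + 1) if alnum[j - 1] and (j == n or not alnum[j])]
    keys = {k for k, e in lexicon.entries.items() if e.entity_class == entity_class}
    matches = []
    for i in starts:
        for j in ends:
            if j > i and normalize_key(text[i:j]) in keys:
                matches.append((i, j))
    chosen, pos = [], 0
    for i, j in sorted(matches, key=lambda m: (m[0], -m[1])):
        if i >= pos:
            chosen.append((i, j))
            pos = j
    return chosen


class TestFindMentions:
    def test_single_entry_full_span(self):
        (m,) = find_mentions("heart disease", lex_of(("heart disease", "D1")), NO_SPELL)
        assert (m.start, m.end, m.surface) == (0, 13, "heart disease")

    def test_longest_match_wins(self):
        lex = lex_of(("lung disease", "D1"), ("disease", "D2"))
        (m,) = find_mentions("lung disease", lex, NO_SPELL)
        assert m.surface == "lung disease" and m.concept_ids == ("D1",)

    def test_matches_respect_word_boundaries(self):
        lex = lex_of(("ulcer", "D1"))
        assert find_mentions("ulcerative text", lex, NO_SPELL) == []
        (m,) = find_mentions("an ulcer.", lex, NO_SPELL)
        assert m.surface == "ulcer"

    def test_boundary_at_hyphen_allows_chemical_prefix(self):
        lex = lex_of(("aspirin", "C1"), entity_class="chemical")
        (m,) = find_mentions("aspirin-associated damage", lex, NO_SPELL,
                             entity_classes=("chemical",))
        assert (m.start, m.end) == (0, 7)

    def test_classes_matched_independently(self):
        lex = Lexicon()
        lex.add(LexiconEntry("toxic hepatitis", "D1", "disease"))
        lex.add(LexiconEntry("toxic", "C1", "chemical"))
        ms = find_mentions("toxic hepatitis", lex, NO_SPELL)
        assert {(m.entity_class, m.surface) for m in ms} == {
            ("disease", "toxic hepatitis"),
            ("chemical", "toxic"),
        }

    def test_mentions_never_overlap_within_class(self):
        rng = random.Random(5)
        vocab = ["toy", "illness", "heart", "lung", "disease", "acute"]
        lex = lex_of(*((t, f"D{i}") for i, t in enumerate(vocab + ["heart disease"])))
        for _ in range(50):
            text = " ".join(rng.choice(vocab) for _ in range(rng.randint(0, 15)))
            ms = find_mentions(text, lex, NO_SPELL)
            for a, b in zip(ms, ms[1:]):
                assert a.end <= b.start
                assert a.surface == text[a.start:a.end]

    def test_matcher_equals_bruteforce_oracle_on_random_fixtures(self):
        rng = random.Random(20240917)
        vocab = ["toy", "illness", "heart", "lung", "disease", "acute",
                 "chronic", "fever", "toyitis", "syndrome"]
        for trial in range(200):
            terms = set()
            for _ in range(rng.randint(1, 8)):
                terms.add(" ".join(rng.sample(vocab, rng.randint(1, 3))))
            lex = lex_of(*((t, f"D{i}") for i, t in enumerate(sorted(terms))))
            words = [rng.choice(vocab + [",", "and", "of"]) for _ in range(rng.randint(1, 25))]
            text = " ".join(words)
            got = [(m.start, m.end) for m in find_mentions(text, lex, NO_SPELL)]
            assert got == brute_force_mentions(text, lex), (trial, text, sorted(terms))

    def test_spelling_off_yields_subset(self):
        lex = lex_of(("hypertension", "D1"), ("diabetes", "D2"))
        text = "hypertenson and diabetes were seen"
        with_spell = {(m.start, m.end) for m in find_mentions(text, lex, MatchConfig())}
        without = {(m.start, m.end) for m in find_mentions(text, lex, NO_SPELL)}
        assert without <= with_spell
        assert (0, 11) in with_spell and (0, 11) not in without


class TestSpellingLookup:
    def test_one_deletion_recovered(self):
        lex = lex_of(("hypertension", "D1"))
        assert spell_tolerant_lookup("hypertenson", lex, MatchConfig()) == "D1"

    def test_digit_edits_barred(self):
        lex = lex_of(("gene2", "D1"))
        assert spell_tolerant_lookup("gene1", lex, MatchConfig(spelling_min_length=5)) is None

    def test_ambiguous_correction_refused(self):
        lex = lex_of(("colitis x", "D1"), ("colitis y", "D2"))
        assert spell_tolerant_lookup("colitis z", lex, MatchConfig()) is None

    def test_short_spans_not_corrected(self):
        lex = lex_of(("fever", "D1"))
        assert spell_tolerant_lookup("fevr", lex, MatchConfig()) is None

    def test_first_character_must_match(self):
        lex = lex_of(("hypertension", "D1"))
        assert spell_tolerant_lookup("typertension", lex, MatchConfig()) is None


class TestComposites:
    def test_heart_and_lung_disease(self):
        lex = lex_of(("heart disease", "D_H"), ("lung disease", "D_L"))
        text = "heart and lung disease"
        mentions = find_mentions(text, lex, NO_SPELL)
        out = detect_composites(text, mentions, lex)
        ids = {cid for m in out for cid in m.concept_ids}
        assert ids == {"D_H", "D_L"}
        comp = next(m for m in out if m.provenance == "composite")
        assert (comp.start, comp.end, comp.surface) == (0, 5, "heart")

    def test_no_composite_without_reconstructed_entry(self):
        lex = lex_of(("lung disease", "D_L"))
        text = "cats and lung disease"
        mentions = find_mentions(text, lex, NO_SPELL)
        out = detect_composites(text, mentions, lex)
        assert out == mentions

    def test_head_or_neck_cancer(self):
        lex = lex_of(("head cancer", "D_H"), ("neck cancer", "D_N"))
        text = "head or neck cancer"
        out = detect_composites(text, find_mentions(text, lex, NO_SPELL), lex)
        assert {cid for m in out for cid in m.concept_ids} == {"D_H", "D_N"}

    def test_existing_mentions_unchanged(self):
        lex = lex_of(("heart disease", "D_H"), ("lung disease", "D_L"))
        text = "heart and lung disease"
        mentions = find_mentions(text, lex, NO_SPELL)
        out = detect_composites(text, mentions, lex)
        assert [m for m in out if m.provenance != "composite"] == mentions


class TestDrugInducedPreference:
    def test_rewrite_and_identity(self):
        m = Mention("d", 0, 4, "akat", "disease", ("ID_BASE",))
        (r,) = prefer_drug_induced([m], {"ID_BASE": "ID_INDUCED"})
        assert r.concept_ids == ("ID_INDUCED",)
        assert prefer_drug_induced([m], {}) == [m]

    def test_chemicals_never_rewritten(self):
        m = Mention("d", 0, 4, "chem", "chemical", ("ID_BASE",))
        assert prefer_drug_induced([m], {"ID_BASE": "X"}) == [m]


class TestChemicalNormalization:
    @pytest.fixture()
    def chem_lex(self):
        return lex_of(("topiramate", "C052342"), ("nitrate", "C_N"),
                      entity_class="chemical")

    def test_exact(self, chem_lex):
        assert normalize_chemical("topiramate", chem_lex) == "C052342"

    def test_plural_stripped(self, chem_lex):
        assert normalize_chemical("nitrates", chem_lex) == "C_N"

    def test_unknown_returns_none(self, chem_lex):
        assert normalize_chemical("unobtainium", chem_lex) is None
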