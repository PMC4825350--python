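"""Sentence handling, entity grouping, pattern matching and relation filters."""

import pytest

from cidminer.corpus import PubTatorDocument
from cidminer.mesh import TreeNumber
from cidminer.ner import Mention, recognize
from cidminer.relations import (
    CAUSED_REGEX,
    CandidateRelation,
    apply_patterns,
    compile_pattern,
    default_patterns,
    extract_document,
    filter_relations,
    group_entities,
    make_config,
    recall_heuristic,
    remove_redundant,
    rule_pos_tagger,
    split_sentences,
    tag_sentence,
)

T = TreeNumber.parse


def rel(chem, dis, doc="d1", origin="p"):
    return CandidateRelation(doc, chem, dis, "c", "s", "evidence", origin)


class TestSentences:
    def test_two_sentences_with_offsets(self):
        s = split_sentences("A causes B. C follows D.")
        assert [(x.text, x.offset) for x in s] == [("A causes B.", 0), ("C follows D.", 12)]

    def test_abbreviation_does_not_split(self):
        s = split_sentences("Drugs, e.g. Aspirin, are chemicals. Also this.")
        assert len(s) == 2
        assert s[0].text.startswith("Drugs, e.g. Aspirin")

    def test_empty_string(self):
        assert split_sentences("") == []

    def test_sentences_cover_nonwhitespace(self):
        text = "One here. Two there! Three?  Four."
        s = split_sentences(text)
        covered = "".join(x.text for x in s)
        assert covered.replace(" ", "") == text.replace(" ", "")


class TestTaggerGrouping:
    def test_coarse_tags(self):
        tags = rule_pos_tagger(["aspirin", "caused", "during", "and", "treatment"])
        assert tags == ["OTHER", "VERB", "ADP_SCONJ", "OTHER", "OTHER"]

    def _mentions(self, text, spans):
        return [
            Mention("d", s, e, text[s:e], cls, (cid,))
            for s, e, cls, cid in spans
        ]

    def test_conjunction_merges_preposition_splits(self):
        text = "Hypohidrosis and hyperthermia during topiramate treatment"
        mentions = self._mentions(text, [
            (0, 12, "disease", "D007007"),
            (17, 29, "disease", "D005334"),
            (37, 47, "chemical", "C052342"),
        ])
        sent = tag_sentence(split_sentences(text)[0])
        groups = group_entities(sent, mentions)
        by_class = {}
        for g in groups:
            by_class.setdefault(g.entity_class, []).append(g)
        assert len(by_class["disease"]) == 1
        assert by_class["disease"][0].concept_ids() == ["D007007", "D005334"]
        assert len(by_class["chemical"]) == 1

    def test_verb_splits_groups(self):
        text = "fever causes fever2"
        mentions = self._mentions(text, [
            (0, 5, "disease", "D1"), (13, 19, "disease", "D2"),
        ])
        sent = tag_sentence(split_sentences(text)[0])
        assert len(group_entities(sent, mentions)) == 2

    def test_single_mention_singleton_group(self):
        text = "fever only"
        sent = tag_sentence(split_sentences(text)[0])
        (g,) = group_entities(sent, self._mentions(text, [(0, 5, "disease", "D1")]))
        assert g.concept_ids() == ["D1"]


class TestPrintedRegex:
    VERBATIM = r".*(-associated|(?<!not |[a-z])(associated with|cause[sd]))(?! no) .*"

    @pytest.mark.parametrize(
        "context,matches",
        [
            (" caused ", True),
            (" causes ", True),
            (" associated with ", True),
            ("-associated ", True),
            (" was associated with ", True),
            (" frequently caused severe ", True),
            (" caused no ", False),
            (" causes no ", False),
            (" was not associated with ", False),
            (" not caused ", False),
            (" because of d ", False),  # [a-z] lookbehind: no match inside words
            (" uncaused ", False),
            (" discussed ", False),
        ],
    )
    def test_verbatim_pattern_behavior(self, context, matches):
        rx = compile_pattern(self.VERBATIM)
        assert bool(rx.fullmatch(context)) is matches

    def test_variable_width_lookbehind_rewrite_is_equivalent(self):
        rx = compile_pattern(r".*(?<!not |[a-z])related to .*")
        assert rx.fullmatch(" was related to ")
        assert not rx.fullmatch(" was not related to ")
        assert not rx.fullmatch(" unrelated to ")


def _annotated(text, lexicon):
    return recognize(text, lexicon, doc_id="d1")


class TestApplyPatterns:
    def _run(self, text, lexicon, patterns=None):
        mentions = _annotated(text, lexicon)
        sent = tag_sentence(split_sentences(text)[0])
        groups = group_entities(sent, mentions)
        return apply_patterns(
            sent,
            [g for g in groups if g.entity_class == "chemical"],
            [g for g in groups if g.entity_class == "disease"],
            patterns or default_patterns(),
        )

    def test_caused_pattern_fires(self, lexicon):
        rels = self._run("Aspirin caused toy carcinoma.", lexicon)
        assert {(r.chemical_id, r.disease_id) for r in rels} == {("D920001", "D910009")}

    def test_negative_lookahead_blocks_caused_no(self, lexicon):
        assert self._run("Aspirin caused no toy carcinoma.", lexicon) == []

    def test_lookbehind_blocks_not_associated(self, lexicon):
        assert self._run("Aspirin was not associated with toy carcinoma.", lexicon) == []

    def test_every_group_member_paired(self, lexicon):
        rels = self._run("Aspirin caused hypohidrosis and fever.", lexicon)
        assert {(r.chemical_id, r.disease_id) for r in rels} == {
            ("D920001", "D007007"),
            ("D920001", "D005334"),
        }


class TestHeuristic:
    def _doc(self, title, abstract=""):
        return PubTatorDocument(doc_id="d1", title=title, abstract=abstract)

    def _mention(self, start, end, cls, cid, surface="x"):
        return Mention("d1", start, end, surface, cls, (cid,))

    def test_title_chemicals_pair_with_all_diseases(self):
        doc = self._doc("chemX report", "diseaseA then diseaseB")
        mentions = [
            self._mention(0, 5, "chemical", "X"),
            self._mention(13, 21, "disease", "A"),
            self._mention(27, 35, "disease", "B"),
        ]
        pairs = {(r.chemical_id, r.disease_id)
                 for r in recall_heuristic(doc, mentions, False)}
        assert pairs == {("X", "A"), ("X", "B")}

    def test_most_frequent_abstract_chemical_tie_breaks_earliest(self):
        doc = self._doc("no chems here", "Y Z Y Z Z Y diseases")
        mentions = [
            self._mention(14, 15, "chemical", "Y"),
            self._mention(16, 17, "chemical", "Z"),
            self._mention(18, 19, "chemical", "Y"),
            self._mention(20, 21, "chemical", "Z"),
            self._mention(22, 23, "chemical", "Z"),
            self._mention(24, 25, "chemical", "Y"),
            self._mention(26, 34, "disease", "A"),
        ]
        pairs = {(r.chemical_id, r.disease_id)
                 for r in recall_heuristic(doc, mentions, False)}
        assert pairs == {("Y", "A")}  # 3-3 tie, Y occurs first

    def test_noop_when_pattern_fired(self):
        doc = self._doc("chemX report", "diseaseA")
        assert recall_heuristic(doc, [], True) == []


class TestFilters:
    def test_blocked_ids_dropped(self, thesaurus):
        rels = [rel("C1", "D010300"), rel("C1", "D910009")]
        kept = filter_relations(rels, thesaurus=thesaurus)
        assert [r.disease_id for r in kept] == ["D910009"]

    def test_blocked_branches_dropped(self, thesaurus):
        rels = [rel("C1", "D910007"), rel("C1", "D910008"), rel("C1", "D910009")]
        kept = filter_relations(rels, thesaurus=thesaurus)
        assert [r.disease_id for r in kept] == ["D910009"]  # C02.*, C16.320.* gone

    def test_unknown_disease_kept(self, thesaurus):
        rels = [rel("C1", "D999999")]
        assert filter_relations(rels, thesaurus=thesaurus) == rels

    def test_idempotent_and_order_insensitive(self, thesaurus):
        rels = [rel("C1", "D910007"), rel("C1", "D910009"), rel("C2", "D010300")]
        once = filter_relations(rels, thesaurus=thesaurus)
        twice = filter_relations(once, thesaurus=thesaurus)
        assert once == twice
        rev = filter_relations(list(reversed(rels)), thesaurus=thesaurus)
        assert set(r.key for r in rev) == set(r.key for r in once)


class TestRedundancy:
    def test_general_disease_dropped(self, thesaurus):
        rels = [rel("C1", "D910010"), rel("C1", "D910009")]  # C04.557.337 vs C04.557
        kept = remove_redundant(rels, thesaurus)
        assert [r.disease_id for r in kept] == ["D910010"]

    def test_drop_specific_direction(self, thesaurus):
        rels = [rel("C1", "D910010"), rel("C1", "D910009")]
        kept = remove_redundant(rels, thesaurus, direction="drop_specific")
        assert [r.disease_id for r in kept] == ["D910009"]

    def test_different_chemicals_never_compared(self, thesaurus):
        rels = [rel("C1", "D910010"), rel("C2", "D910009")]
        assert remove_redundant(rels, thesaurus) == rels

    def test_single_relation_unchanged(self, thesaurus):
        rels = [rel("C1", "D910009")]
        assert remove_redundant(rels, thesaurus) == rels

    def test_no_refining_pair_survives(self, thesaurus):
        import itertools, random as rnd

        rng = rnd.Random(11)
        disease_ids = [d for d in thesaurus.concepts if thesaurus.concepts[d].tree_numbers]
        for _ in range(30):
            rels = [rel("C1", d) for d in rng.sample(disease_ids, rng.randint(2, 6))]
            kept = remove_redundant(rels, thesaurus)
            from cidminer.mesh import entirely_refines

            for a, b in itertools.permutations(kept, 2):
                ta = thesaurus.concepts[a.disease_id].tree_numbers
                tb = thesaurus.concepts[b.disease_id].tree_numbers
                assert not (entirely_refines(ta, tb) and not entirely_refines(tb, ta))


class TestExtractDocument:
    def test_worked_example_title(self, lexicon, thesaurus):
        doc = PubTatorDocument(
            doc_id="23427516",
            title="Hypohidrosis and hyperthermia during topiramate treatment in children.",
        )
        mentions = recognize(doc.text, lexicon, doc_id=doc.doc_id)
        rels = extract_document(doc, mentions, make_config("patterns", thesaurus))
        assert {(r.chemical_id, r.disease_id) for r in rels} == {
            ("C052342", "D007007"),
            ("C052342", "D005334"),
        }

    def test_ameliorative_phrasing_is_not_a_cid(self, lexicon, thesaurus):
        doc = PubTatorDocument(
            doc_id="x", title="Fever improved after taking aspirin."
        )
        mentions = recognize(doc.text, lexicon, doc_id="x")
        assert extract_document(doc, mentions, make_config("patterns", thesaurus)) == []

    def test_document_without_mentions(self, thesaurus):
        doc = PubTatorDocument(doc_id="x", title="Nothing to see here.")
        assert extract_document(doc, [], make_config("patterns", thesaurus)) == []

    def test_filters_config_output_is_subset_of_patterns(self, lexicon, thesaurus):
        from cidminer.fixtures import PlantedCorpusSpec, generate_planted_corpus
        from cidminer.pipeline import process_corpus

        docs, _ = generate_planted_corpus(PlantedCorpusSpec(n_docs=30, seed=13))
        _, base = process_corpus(docs, lexicon, make_config("patterns", thesaurus))
        _, filt = process_corpus(docs, lexicon, make_config("patterns+filters", thesaurus))
        assert {r.key for r in filt} <= {r.key for r in base}

    def test_heuristic_config_recovers_cross_sentence(self, lexicon, thesaurus):
        doc = PubTatorDocument(
            doc_id="x",
            title="Aspirin pharmacology.",
            abstract="Unrelated sentence one. Hypohidrosis was later observed.",
        )
        mentions = recognize(doc.text, lexicon, doc_id="x")
        rels = extract_document(
            doc, mentions, make_config("patterns+filters+heuristic", thesaurus)
        )
        assert {(r.chemical_id, r.disease_id) for r in rels} == {("D920001", "D007007")}
        assert all(r.origin == "heuristic" for r in rels)

    def test_opposite_classes_only(self, lexicon, thesaurus):
        from cidminer.fixtures import PlantedCorpusSpec, generate_planted_corpus
        from cidminer.pipeline import process_corpus

        docs, _ = generate_planted_corpus(PlantedCorpusSpec(n_docs=20, seed=3))
        _, rels = process_corpus(docs, lexicon, make_config("patterns", thesaurus))
        chem_ids = {"D920001", "D920002", "D920003", "D920004", "C052342"}
        for r in rels:
            assert r.chemical_id in chem_ids
            assert r.disease_id not in chem_ids
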