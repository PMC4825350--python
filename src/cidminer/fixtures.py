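"""Deterministic toy inputs for every pipeline stage.

All artifacts are generated in memory, byte-identical across runs, and use a
reserved D9xxxxx/C9xxxxx MeSH ID range — except three IDs kept literal for
the worked example (topiramate C052342, hypohidrosis D007007, fever/
hyperthermia D005334) and the five vague-disease IDs used by the relation
filter.  The planted corpus generator writes abstracts from per-pattern
sentence templates with known chemical/disease slots, including negated
variants that must *not* be extracted, and returns the expected relation set
alongside the gold-annotated documents.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import PubTatorDocument
from .lexicon import Lexicon, build_lexicon, mappings_from_concepts
from .mesh import MeshThesaurus, parse_descriptors, parse_supplementary
from .ner import Mention

__all__ = [
    "make_toy_thesaurus",
    "make_toy_obo",
    "make_toy_wiki_dump",
    "make_toy_medline",
    "make_ignore_lists",
    "toy_thesaurus",
    "toy_lexicon",
    "PlantedCorpusSpec",
    "generate_planted_corpus",
    "WIKI_EXPECTED_MAPPINGS",
]


def _descriptor(uid: str, name: str, trees: list[str], entry_terms: list[str] = ()) -> str:
    tree_xml = "".join(f"<TreeNumber>{t}</TreeNumber>" for t in trees)
    terms = "".join(
        f"<Term><String>{t}</String></Term>" for t in [name, *entry_terms]
    )
    return (
        "<DescriptorRecord>"
        f"<DescriptorUI>{uid}</DescriptorUI>"
        f"<DescriptorName><String>{name}</String></DescriptorName>"
        + (f"<TreeNumberList>{tree_xml}</TreeNumberList>" if trees else "")
        + f"<ConceptList><Concept><TermList>{terms}</TermList></Concept></ConceptList>"
        "</DescriptorRecord>"
    )


def _supplementary(uid: str, name: str, mapped: list[str], entry_terms: list[str] = ()) -> str:
    mapped_xml = "".join(
        "<HeadingMappedTo><DescriptorReferredTo>"
        f"<DescriptorUI>{m}</DescriptorUI>"
        "</DescriptorReferredTo></HeadingMappedTo>"
        for m in mapped
    )
    terms = "".join(f"<Term><String>{t}</String></Term>" for t in [name, *entry_terms])
    return (
        "<SupplementalRecord>"
        f"<SupplementalRecordUI>{uid}</SupplementalRecordUI>"
        f"<SupplementalRecordName><String>{name}</String></SupplementalRecordName>"
        f"<HeadingMappedToList>{mapped_xml}</HeadingMappedToList>"
        f"<ConceptList><Concept><TermList>{terms}</TermList></Concept></ConceptList>"
        "</SupplementalRecord>"
    )


def make_toy_thesaurus() -> tuple[bytes, bytes]:
    """Descriptor and supplementary XML covering the selection edge cases:
    trees in C, F03, the excluded branches C23.550.291/C23.550.260/C26, a
    multi-axial rescue, category D chemicals, a nested carcinoma pair for
    redundancy, the drug-induced preference pair, the filter-blocked IDs and
    the worked-example trio."""
    descriptors = [
        # worked-example diseases (literal IDs)
        _descriptor("D007007", "Hypohidrosis", ["C23.888.119.344"], ["hypohidrosis"]),
        _descriptor("D005334", "Fever", ["C23.888.119.846"], ["Hyperthermia", "Pyrexia"]),
        # generic toys
        _descriptor("D910001", "ToyDisease", ["C99.100"], ["toy illness"]),
        _descriptor("D910002", "Toy Disease Attribute", ["C23.550.291.500"]),
        _descriptor("D910003", "Toy Death", ["C23.550.260.100"]),
        _descriptor("D910004", "Toy Injury", ["C26.120"]),
        _descriptor("D910005", "Toy Injury Neoplasm", ["C26.120", "C04.557"]),
        _descriptor("D910006", "Toy Mental Disorder", ["F03.600"], ["toy plague"]),
        _descriptor("D910007", "Toy Viral Fever", ["C02.100"]),
        _descriptor("D910008", "Toy Inborn Error", ["C16.320.100"]),
        _descriptor("D910009", "Toy Carcinoma", ["C04.557"]),
        _descriptor("D910010", "Toy Adenocarcinoma", ["C04.557.337"]),
        _descriptor("D910011", "Toy Akathisia", ["C10.228"]),
        _descriptor("D910012", "Toy Akathisia, Drug-Induced", ["C25.100.100"]),
        _descriptor("D910013", "Abnormality, Congenital", ["C16.131"]),
        # the five vague diseases blocked by the relation filter (literal IDs)
        _descriptor("D064420", "Toy Adverse Drug Event", ["C25.100"]),
        _descriptor("D010300", "Toy Vague Disease A", ["C23.888.100"]),
        _descriptor("D003643", "Toy Vague Disease B", ["C23.550.300"]),
        _descriptor("D066126", "Toy Vague Disease C", ["C23.888.200"]),
        _descriptor("D020258", "Toy Vague Disease D", ["C25.200"]),
        # chemicals (category D)
        _descriptor("D920001", "Aspirin", ["D02.455"], ["acetylsalicylic acid"]),
        _descriptor("D920002", "Streptozocin", ["D09.408"]),
        _descriptor("D920003", "Nitrate", ["D01.248"]),
        _descriptor("D920004", "Toy Sugar", ["D09.400"]),
    ]
    supplementary = [
        _supplementary("C052342", "topiramate", ["*D920004"]),
        _supplementary("C900001", "toyamide syndrome", ["D910001"]),
        _supplementary("C900002", "unrelated compound", ["D999999"]),
    ]
    desc_xml = (
        "<?xml version=\"1.0\"?>\n<DescriptorRecordSet>"
        + "".join(descriptors)
        + "</DescriptorRecordSet>\n"
    ).encode()
    supp_xml = (
        "<?xml version=\"1.0\"?>\n<SupplementalRecordSet>"
        + "".join(supplementary)
        + "</SupplementalRecordSet>\n"
    ).encode()
    return desc_xml, supp_xml


def make_toy_obo() -> str:
    """A tiny Disease Ontology file: one MeSH-linked stanza, one without a
    MeSH xref and one obsolete stanza."""
    return """format-version: 1.2
ontology: toy-disease-ontology

[Term]
id: DOID:9100001
name: toyitis
synonym: "toy inflammation" EXACT []
synonym: "toyitis disorder" RELATED []
xref: MESH:D910001

[Term]
id: DOID:9100002
name: unmapped malady
xref: ICD10CM:Z99

[Term]
id: DOID:9100003
name: retired toy disease
xref: MESH:D910006
is_obsolete: true
"""


def _wiki_page(title: str, text: str = "", redirect: str | None = None) -> str:
    if redirect is not None:
        return (
            f"<page><title>{title}</title><redirect title=\"{redirect}\" />"
            f"<revision><text>#REDIRECT [[{redirect}]]</text></revision></page>"
        )
    return f"<page><title>{title}</title><revision><text>{text}</text></revision></page>"


def make_toy_wiki_dump() -> bytes:
    """A pages-articles dump with infobox pages (ID and tree-number link-outs),
    redirects, ignore-list hits and a title-match augmentation case."""
    pages = [
        _wiki_page("Toyitis", "{{Infobox disease | MeshID = D910001 }}\nToyitis is a disease."),
        _wiki_page("Toy disease", redirect="Toyitis"),
        _wiki_page("Toyitic", redirect="Toyitis"),
        _wiki_page("History of toyitis", redirect="Toyitis"),
        _wiki_page(
            "Feverish toy",
            "{{Infobox symptom | MeshNumber = C23.888.119.846 }}\nA symptom page.",
        ),
        _wiki_page("Toy fever", redirect="Feverish toy"),
        _wiki_page("Toy pyrexia", redirect="Feverish toy"),
        _wiki_page("Toy plague", "{{Infobox medical condition | MeSH = D910006 }}\nAnother."),
        _wiki_page("MUMPS", "{{Infobox disease | MeshID = D910006 }}\nA programming language."),
        _wiki_page("M-u-m-p-s", redirect="MUMPS"),
        _wiki_page("Toyville", "{{Infobox settlement | population = 5 }}\nA town."),
        _wiki_page("ToyDisease", "ToyDisease is known from the toy literature."),
        _wiki_page("Toyopathy", redirect="ToyDisease"),
    ]
    return (
        "<mediawiki>" + "".join(pages) + "</mediawiki>"
    ).encode()


# harvest_wiki output on the toy dump with the shipped ignore lists
WIKI_EXPECTED_MAPPINGS = {
    ("Toyitis", "D910001", "wiki_title"),
    ("Feverish toy", "D005334", "wiki_title"),
    ("Toy plague", "D910006", "wiki_title"),
    ("Toy disease", "D910001", "wiki_redirect"),
    ("Toyitic", "D910001", "wiki_redirect"),
    ("Toy fever", "D005334", "wiki_redirect"),
    ("Toy pyrexia", "D005334", "wiki_redirect"),
}


def make_ignore_lists() -> tuple[str, str]:
    """(redirect ignore, title ignore) config file contents."""
    redirect_ignore = "# non-semantic redirects\nHistory of toyitis\n"
    title_ignore = "# pages that are not diseases\nMUMPS  # a programming language\n"
    return redirect_ignore, title_ignore


def make_toy_medline() -> bytes:
    """MEDLINE citation XML: title+abstract, title-only, two abstract
    segments, and a record without a title."""
    return b"""<?xml version="1.0"?>
<MedlineCitationSet>
<MedlineCitation><PMID>23427516</PMID><Article>
<ArticleTitle>Hypohidrosis and hyperthermia during topiramate treatment in children.</ArticleTitle>
</Article></MedlineCitation>
<MedlineCitation><PMID>90000001</PMID><Article>
<ArticleTitle>Toy title.</ArticleTitle>
<Abstract><AbstractText>First segment.</AbstractText><AbstractText>Second segment.</AbstractText></Abstract>
</Article></MedlineCitation>
<MedlineCitation><PMID>90000002</PMID><Article>
</Article></MedlineCitation>
</MedlineCitationSet>
"""


def toy_thesaurus() -> tuple[MeshThesaurus, list]:
    """(thesaurus built from toy descriptors, toy supplementary records)."""
    desc_xml, supp_xml = make_toy_thesaurus()
    thesaurus = MeshThesaurus.from_concepts(parse_descriptors(desc_xml))
    return thesaurus, parse_supplementary(supp_xml)


def toy_lexicon() -> tuple[Lexicon, MeshThesaurus]:
    """Combined disease+chemical lexicon from the toy thesaurus."""
    from .mesh import select_chemical_concepts, select_disease_concepts

    thesaurus, supplementary = toy_thesaurus()
    disease = build_lexicon(
        [("mesh", mappings_from_concepts(select_disease_concepts(thesaurus, supplementary)))],
        entity_class="disease",
    )
    chemical = build_lexicon(
        [("mesh", mappings_from_concepts(select_chemical_concepts(thesaurus, supplementary)))],
        entity_class="chemical",
    )
    combined = Lexicon(entries={**disease.entries, **chemical.entries})
    return combined, thesaurus


# --- planted corpus --------------------------------------------------------

CHEM, DIS = "@C@", "@D@"

# (pattern name, positive template, optional negated template); templates are
# part lists with CHEM/DIS slots.  Negated variants use the guard phrases the
# patterns must reject.
DEFAULT_TEMPLATES: tuple[tuple[str, list[str], list[str] | None], ...] = (
    ("chemical_caused",
     [CHEM, " caused ", DIS, " in the study group."],
     [CHEM, " caused no ", DIS, " in the study group."]),
    ("chemical_caused",
     [CHEM, "-associated ", DIS, " was reported."],
     [CHEM, " was not associated with ", DIS, " in this cohort."]),
    ("disease_caused_by",
     [DIS, " caused by ", CHEM, " was reported."],
     [DIS, " was not caused by ", CHEM, " in this cohort."]),
    ("disease_after_or_during",
     [DIS, " developed during ", CHEM, " therapy."],
     [DIS, " improved during ", CHEM, " therapy."]),
    ("disease_after_or_while_taking",
     [DIS, " occurred after taking ", CHEM, "."],
     [DIS, " resolved after taking ", CHEM, "."]),
    ("chemical_disease_adjacency",
     [CHEM, " ", DIS, " is a well recognized problem."],
     None),
    ("relationship_between_chem_and",
     ["The relationship between ", CHEM, " and ", DIS, " was studied."],
     None),
    ("induction_of_by_or_with",
     ["Induction of ", DIS, " by ", CHEM, " was demonstrated."],
     None),
    ("negative_effects_caused_by",
     ["Negative effects caused by ", CHEM, " include ", DIS, "."],
     None),
    ("disease_effect_of",
     [DIS, " is a common side effect of ", CHEM, "."],
     None),
    ("disease_complications_of",
     [DIS, " was one of the complications of ", CHEM, " therapy."],
     None),
    ("disease_in_person_taking",
     [DIS, " in patients taking ", CHEM, " was frequent."],
     None),
)

# pools drawn from the toy thesaurus; the disease trees are chosen pairwise
# non-nested so redundancy removal never trims a planted relation
DEFAULT_CHEM_TERMS = (
    ("aspirin", "D920001"),
    ("streptozocin", "D920002"),
    ("topiramate", "C052342"),
    ("nitrate", "D920003"),
)
DEFAULT_DISEASE_TERMS = (
    ("hypohidrosis", "D007007"),
    ("fever", "D005334"),
    ("toy illness", "D910001"),
    ("toy carcinoma", "D910009"),
    ("toy plague", "D910006"),
)


@dataclass
class PlantedCorpusSpec:
    n_docs: int = 100
    templates: tuple = DEFAULT_TEMPLATES
    chem_terms: tuple = DEFAULT_CHEM_TERMS
    disease_terms: tuple = DEFAULT_DISEASE_TERMS
    negation_rate: float = 0.2
    seed: int = 0
    sentences_per_doc: tuple[int, int] = (1, 3)
    filler: str = "The cohort was followed for two years."


def _instantiate(parts: list[str], chem: tuple[str, str], dis: tuple[str, str]):
    """Render one template: (sentence text, entity spans within sentence)."""
    text = ""
    spans: list[tuple[int, int, str, str]] = []  # start, end, class, id
    for part in parts:
        if part == CHEM:
            spans.append((len(text), len(text) + len(chem[0]), "chemical", chem[1]))
            text += chem[0]
        elif part == DIS:
            spans.append((len(text), len(text) + len(dis[0]), "disease", dis[1]))
            text += dis[0]
        else:
            text += part
    if text and text[0].islower():
        text = text[0].upper() + text[1:]
    return text, spans


def generate_planted_corpus(
    spec: PlantedCorpusSpec,
) -> tuple[list[PubTatorDocument], set[tuple[str, str, str]]]:
    """Seed-deterministic corpus with planted CID relations.

    Each document's abstract holds one to three template sentences (plus a
    filler sentence); with probability ``negation_rate`` a negatable template
    is rendered in its negated form and excluded from the expected relation
    set.  Gold annotations carry exact offsets; gold CID pairs equal the
    expected (non-negated) relations.
    """
    if not spec.chem_terms or not spec.disease_terms:
        raise ValueError("empty term pools")
    rng = random.Random(spec.seed)
    docs: list[PubTatorDocument] = []
    expected: set[tuple[str, str, str]] = set()
    lo, hi = spec.sentences_per_doc
    for k in range(spec.n_docs):
        doc_id = f"9{spec.seed % 1000:03d}{k:04d}"
        title = f"Observational safety report {k}."
        sentences: list[tuple[str, list]] = []
        for _ in range(rng.randint(lo, hi)):
            name, positive, negated = spec.templates[rng.randrange(len(spec.templates))]
            chem = spec.chem_terms[rng.randrange(len(spec.chem_terms))]
            dis = spec.disease_terms[rng.randrange(len(spec.disease_terms))]
            negate = negated is not None and rng.random() < spec.negation_rate
            text, spans = _instantiate(negated if negate else positive, chem, dis)
            sentences.append((text, spans))
            if not negate:
                expected.add((doc_id, chem[1], dis[1]))
        sentences.append((spec.filler, []))
        abstract = ""
        annotations: list[Mention] = []
        base = len(title) + 1
        for text, spans in sentences:
            if abstract:
                abstract += " "
            offset = base + len(abstract)
            abstract += text
            for s, e, cls, cid in spans:
                annotations.append(
                    Mention(
                        doc_id=doc_id,
                        start=offset + s,
                        end=offset + e,
                        surface=(title + " " + abstract)[offset + s : offset + e],
                        entity_class=cls,
                        concept_ids=(cid,),
                    )
                )
        doc = PubTatorDocument(
            doc_id=doc_id,
            title=title,
            abstract=abstract,
            annotations=annotations,
            cid_pairs={(c, d) for (i, c, d) in expected if i == doc_id},
        )
        docs.append(doc)
    return docs, expected
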