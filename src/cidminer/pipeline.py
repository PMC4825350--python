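"""End-to-end document processing: recognition then relation extraction."""

from __future__ import annotations

from .corpus import PubTatorDocument
from .lexicon import Lexicon
from .mesh import MeshThesaurus
from .ner import MatchConfig, recognize
from .relations import CandidateRelation, ExtractionConfig, extract_document

__all__ = ["process_document", "process_corpus"]


def process_document(
    doc: PubTatorDocument,
    lexicon: Lexicon,
    config: ExtractionConfig,
    match_config: MatchConfig | None = None,
    drug_induced_table: dict[str, str] | None = None,
) -> tuple[PubTatorDocument, list[CandidateRelation]]:
    """Annotate one title+abstract document and extract its CID relations.

    Returns a predicted document (mentions as annotations, relations as CID
    pairs) plus the relation objects with their evidence passages.
    """
    mentions = recognize(
        doc.text, lexicon, match_config, doc_id=doc.doc_id,
        drug_induced_table=drug_induced_table,
    )
    relations = extract_document(doc, mentions, config)
    pred = PubTatorDocument(
        doc_id=doc.doc_id,
        title=doc.title,
        abstract=doc.abstract,
        annotations=mentions,
        cid_pairs={(r.chemical_id, r.disease_id) for r in relations},
    )
    return pred, relations


def process_corpus(
    docs,
    lexicon: Lexicon,
    config: ExtractionConfig,
    match_config: MatchConfig | None = None,
    drug_induced_table: dict[str, str] | None = None,
) -> tuple[list[PubTatorDocument], list[CandidateRelation]]:
    preds: list[PubTatorDocument] = []
    relations: list[CandidateRelation] = []
    for doc in docs:
        pred, rels = process_document(doc, lexicon, config, match_config, drug_induced_table)
        preds.append(pred)
        relations.extend(rels)
    return preds, relations
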