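"""PubTator (BC5CDR dialect) and MEDLINE citation I/O plus P/R/F1 evaluation.

A PubTator document is a title line ``pmid|t|...``, an abstract line
``pmid|a|...``, tab-separated annotation lines (pmid, start, end, surface,
type, concept ID) with offsets into ``title + " " + abstract``, optional
``pmid<TAB>CID<TAB>chemID<TAB>diseaseID`` relation lines, and a blank
separator line.  Unnormalized annotations carry the ID ``-1``; composite
annotations join several MeSH IDs with ``|``.

Evaluation is document-level over concept IDs: disease NER over distinct
(document, disease MeSH ID) pairs, CID over distinct (document, chemical ID,
disease ID) triples.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

from lxml import etree

from .ner import Mention
from .relations import CandidateRelation

logger = logging.getLogger(__name__)

__all__ = [
    "PubTatorDocument",
    "EvalResult",
    "read_pubtator",
    "write_pubtator",
    "read_medline",
    "write_relation_tsv",
    "evaluate_dner",
    "evaluate_cid",
]


@dataclass
class PubTatorDocument:
    doc_id: str
    title: str
    abstract: str = ""
    annotations: list[Mention] = field(default_factory=list)
    cid_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def text(self) -> str:
        return self.title + (" " + self.abstract if self.abstract else "")


_CLASS_FROM_TYPE = {"chemical": "chemical", "disease": "disease"}
_TYPE_FROM_CLASS = {"chemical": "Chemical", "disease": "Disease"}


def read_pubtator(stream: Union[str, IO[str]]) -> list[PubTatorDocument]:
    """Parse a PubTator-format corpus; offset/surface mismatches are errors."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    docs: list[PubTatorDocument] = []
    current: PubTatorDocument | None = None
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current is not None:
                docs.append(current)
                current = None
            continue
        m = re.match(r"^([^|\t]+)\|([ta])\|(.*)$", line)
        if m:
            doc_id, kind, text = m.groups()
            if current is None or current.doc_id != doc_id:
                if current is not None:
                    docs.append(current)
                current = PubTatorDocument(doc_id=doc_id, title="")
            if kind == "t":
                current.title = text
            else:
                current.abstract = text
            continue
        parts = line.split("\t")
        if current is None or parts[0] != current.doc_id:
            raise ValueError(f"line {lineno}: annotation outside its document block")
        if len(parts) == 4 and parts[1] == "CID":
            current.cid_pairs.add((parts[2], parts[3]))
        elif len(parts) >= 6:
            _, start, end, surface, ann_type, concept = parts[:6]
            start, end = int(start), int(end)
            slice_ = current.text[start:end]
            if slice_ != surface:
                raise ValueError(
                    f"doc {current.doc_id} line {lineno}: offsets [{start},{end}) "
                    f"give {slice_!r}, annotation says {surface!r}"
                )
            cls = _CLASS_FROM_TYPE.get(ann_type.lower(), ann_type.lower())
            current.annotations.append(
                Mention(
                    doc_id=current.doc_id,
                    start=start,
                    end=end,
                    surface=surface,
                    entity_class=cls,
                    concept_ids=tuple(concept.split("|")),
                )
            )
        else:
            raise ValueError(f"line {lineno}: unrecognized PubTator line {line!r}")
    if current is not None:
        docs.append(current)
    return docs


def write_pubtator(docs: Iterable[PubTatorDocument], stream: IO[str]) -> None:
    """Write documents in PubTator format (inverse of :func:`read_pubtator`)."""
    for doc in docs:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for ann in doc.annotations:
            ann_type = _TYPE_FROM_CLASS.get(ann.entity_class, ann.entity_class.capitalize())
            concept = "|".join(ann.concept_ids)
            stream.write(
                f"{doc.doc_id}\t{ann.start}\t{ann.end}\t{ann.surface}\t{ann_type}\t{concept}\n"
            )
        for chem, dis in sorted(doc.cid_pairs):
            stream.write(f"{doc.doc_id}\tCID\t{chem}\t{dis}\n")
        stream.write("\n")


def read_medline(stream: Union[str, bytes, IO[bytes]]) -> Iterator[PubTatorDocument]:
    """Stream documents out of MEDLINE citation XML.

    Multiple AbstractText segments are joined with single spaces; records
    without a title are skipped with a warning.  Where no abstract exists the
    document carries the title only.
    """
    if isinstance(stream, (str, bytes)):
        stream = io.BytesIO(stream.encode() if isinstance(stream, str) else stream)
    for _event, elem in etree.iterparse(stream, events=("end",), tag="MedlineCitation"):
        pmid = elem.findtext("PMID")
        title = elem.findtext("Article/ArticleTitle")
        if not title:
            logger.warning("MEDLINE record %s has no title; skipped", pmid)
            elem.clear(keep_tail=True)
            continue
        segments = [
            t.text.strip()
            for t in elem.iterfind("Article/Abstract/AbstractText")
            if t.text and t.text.strip()
        ]
        yield PubTatorDocument(
            doc_id=(pmid or "").strip(), title=title.strip(), abstract=" ".join(segments)
        )
        elem.clear(keep_tail=True)


_WS = re.compile(r"[\t\r\n]+")


def write_relation_tsv(
    relations: Iterable[CandidateRelation], stream: IO[str], header: bool = False
) -> None:
    """Six tab-separated columns: pmid, chemical MeSH ID, disease MeSH ID,
    chemical surface, disease surface, evidence passage."""
    if header:
        stream.write(
            "pmid\tchemical_mesh_id\tdisease_mesh_id\tchemical_name\tdisease_name\tpassage\n"
        )
    for rel in relations:
        fields = [
            rel.doc_id, rel.chemical_id, rel.disease_id,
            rel.chemical_surface, rel.disease_surface, rel.evidence,
        ]
        stream.write("\t".join(_WS.sub(" ", f) for f in fields) + "\n")


@dataclass(frozen=True)
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @classmethod
    def from_sets(cls, gold: set, pred: set) -> "EvalResult":
        return cls(
            true_positives=len(gold & pred),
            false_positives=len(pred - gold),
            false_negatives=len(gold - pred),
        )


def _disease_id_pairs(docs: Iterable[PubTatorDocument], drop_unnormalized: bool) -> set:
    pairs = set()
    for doc in docs:
        for ann in doc.annotations:
            if ann.entity_class != "disease":
                continue
            for cid in ann.concept_ids:
                if drop_unnormalized and cid == "-1":
                    continue
                pairs.add((doc.doc_id, cid))
    return pairs


def evaluate_dner(
    gold: Iterable[PubTatorDocument], pred: Iterable[PubTatorDocument]
) -> EvalResult:
    """Disease concept-ID recognition over distinct (doc, MeSH ID) pairs.

    Unnormalized gold IDs are excluded; unnormalized predictions count as
    false positives.  Composite IDs count once per component ID.
    """
    return EvalResult.from_sets(
        _disease_id_pairs(gold, drop_unnormalized=True),
        _disease_id_pairs(pred, drop_unnormalized=False),
    )


def evaluate_cid(
    gold: Iterable[PubTatorDocument], pred: Iterable[PubTatorDocument]
) -> EvalResult:
    """CID extraction over distinct (doc, chemical ID, disease ID) triples."""
    def triples(docs):
        return {(d.doc_id, c, dis) for d in docs for (c, dis) in d.cid_pairs}

    return EvalResult.from_sets(triples(gold), triples(pred))
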