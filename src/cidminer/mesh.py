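"""MeSH thesaurus handling: descriptor/supplementary parsing, tree-number algebra,
and selection of the disease and chemical concept subsets.

MeSH descriptors carry one or more *tree numbers* — dot-separated paths such as
``C04.557.337`` locating the concept in the poly-hierarchy.  Disease concepts
are those with a tree number under category ``C`` (Diseases) or under ``F03``
(Mental Disorders), excluding branches that are not diseases by most
definitions: ``C23.550.291`` (Disease attributes), ``C23.550.260`` (Death) and
``C26`` (Wounds and Injuries).  Chemical concepts live under category ``D``.
Supplementary concept records (C-prefixed IDs) have no tree numbers of their
own; they are selected through the descriptors they map to, but keep their own
IDs (e.g. topiramate is C052342).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from lxml import etree

__all__ = [
    "TreeNumber",
    "MeshConcept",
    "MeshThesaurus",
    "MeshParseError",
    "parse_descriptors",
    "parse_supplementary",
    "in_branch",
    "entirely_refines",
    "select_disease_concepts",
    "select_chemical_concepts",
    "DISEASE_BRANCHES",
    "DISEASE_EXCLUDED_BRANCHES",
    "CHEMICAL_BRANCHES",
]


class MeshParseError(ValueError):
    """Raised for malformed MeSH XML input."""


@dataclass(frozen=True, order=True)
class TreeNumber:
    """A MeSH tree number, e.g. ``C23.550.291`` -> segments (C23, 550, 291)."""

    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("tree number needs at least one segment")
        first = self.segments[0]
        if not (first and first[0].isalpha() and first[0].isupper()):
            raise ValueError(f"tree number must start with a category letter: {first!r}")

    @classmethod
    def parse(cls, s: str) -> "TreeNumber":
        return cls(tuple(s.strip().split(".")))

    def __str__(self) -> str:
        return ".".join(self.segments)

    def __repr__(self) -> str:  # compact in test output
        return f"TreeNumber({str(self)!r})"


def in_branch(t: TreeNumber, branch: TreeNumber) -> bool:
    """True iff ``t`` lies inside ``branch`` (segment-wise prefix; equality counts).

    Note this is a *segment* comparison: C23.55 is not in C23.5.
    """
    if len(branch.segments) > len(t.segments):
        return False
    return t.segments[: len(branch.segments)] == branch.segments


def entirely_refines(a: Iterable[TreeNumber], b: Iterable[TreeNumber]) -> bool:
    """True iff every tree number in ``a`` lies inside some branch in ``b``.

    Used to detect redundant relationships: a disease whose tree numbers are
    entirely refinements of another disease's adds no independent information.
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("entirely_refines requires non-empty tree-number sets")
    return all(any(in_branch(t, u) for u in b) for t in a)


@dataclass
class MeshConcept:
    """A MeSH descriptor (D-prefixed) or supplementary record (C-prefixed)."""

    id: str
    preferred_name: str
    terms: set[str] = field(default_factory=set)
    tree_numbers: set[TreeNumber] = field(default_factory=set)
    mapped_to: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("MeshConcept requires a non-empty id")
        self.terms.add(self.preferred_name)

    def __hash__(self) -> int:
        return hash(self.id)


@dataclass
class MeshThesaurus:
    """Concepts indexed by ID plus the inverse tree-number index."""

    concepts: dict[str, MeshConcept] = field(default_factory=dict)
    tree_index: dict[TreeNumber, str] = field(default_factory=dict)

    @classmethod
    def from_concepts(cls, concepts: Iterable[MeshConcept]) -> "MeshThesaurus":
        th = cls()
        for c in concepts:
            if c.id in th.concepts:
                raise MeshParseError(f"duplicate MeSH ID {c.id}")
            th.concepts[c.id] = c
            for t in c.tree_numbers:
                th.tree_index[t] = c.id
        return th

    def by_tree(self, t: TreeNumber) -> MeshConcept | None:
        cid = self.tree_index.get(t)
        return self.concepts.get(cid) if cid is not None else None


# --- XML parsing -----------------------------------------------------------

Stream = Union[str, bytes, IO[bytes]]


def _iterparse(stream: Stream, tag: str):
    import io

    if isinstance(stream, (str, bytes)):
        stream = io.BytesIO(stream.encode() if isinstance(stream, str) else stream)
    try:
        for _event, elem in etree.iterparse(stream, events=("end",), tag=tag):
            yield elem
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise MeshParseError(f"malformed XML near byte offset {getattr(exc, 'position', '?')}: {exc}") from exc


def _text(elem, path: str) -> str | None:
    node = elem.find(path)
    return node.text.strip() if node is not None and node.text else None


def _collect_terms(record) -> set[str]:
    terms: set[str] = set()
    for term in record.iterfind(".//ConceptList/Concept/TermList/Term/String"):
        if term.text:
            terms.add(term.text.strip())
    return terms


def parse_descriptors(stream: Stream) -> list[MeshConcept]:
    """Parse a MeSH descriptor XML file into concepts, input order preserved.

    Collects DescriptorUI, DescriptorName, all entry terms and all tree
    numbers; unknown elements are ignored.  Duplicate DescriptorUI is a hard
    error.
    """
    concepts: list[MeshConcept] = []
    seen: set[str] = set()
    for rec in _iterparse(stream, "DescriptorRecord"):
        uid = _text(rec, "DescriptorUI")
        name = _text(rec, "DescriptorName/String")
        if not uid:
            raise MeshParseError("DescriptorRecord without DescriptorUI")
        if uid in seen:
            raise MeshParseError(f"duplicate DescriptorUI {uid}")
        seen.add(uid)
        trees = {
            TreeNumber.parse(tn.text)
            for tn in rec.iterfind("TreeNumberList/TreeNumber")
            if tn.text
        }
        concepts.append(
            MeshConcept(
                id=uid,
                preferred_name=name or uid,
                terms=_collect_terms(rec),
                tree_numbers=trees,
            )
        )
    return concepts


def parse_supplementary(stream: Stream) -> list[MeshConcept]:
    """Parse MeSH supplementary concept records.

    ``mapped_to`` holds the descriptor IDs referenced in HeadingMappedToList;
    a leading ``*`` (the official marker for the primary mapping) is stripped.
    """
    concepts: list[MeshConcept] = []
    for rec in _iterparse(stream, "SupplementalRecord"):
        uid = _text(rec, "SupplementalRecordUI")
        if not uid:
            raise MeshParseError("SupplementalRecord without SupplementalRecordUI")
        name = _text(rec, "SupplementalRecordName/String")
        mapped: set[str] = set()
        for d in rec.iterfind("HeadingMappedToList/HeadingMappedTo/DescriptorReferredTo/DescriptorUI"):
            if d.text:
                mapped.add(d.text.strip().lstrip("*"))
        concepts.append(
            MeshConcept(
                id=uid,
                preferred_name=name or uid,
                terms=_collect_terms(rec),
                mapped_to=mapped,
            )
        )
    return concepts


# --- concept selection -----------------------------------------------------

DISEASE_BRANCHES = (TreeNumber.parse("C"), TreeNumber.parse("F03"))
DISEASE_EXCLUDED_BRANCHES = (
    TreeNumber.parse("C23.550.291"),  # Disease attributes
    TreeNumber.parse("C23.550.260"),  # Death
    TreeNumber.parse("C26"),          # Wounds and Injuries
)
CHEMICAL_BRANCHES = (TreeNumber.parse("D"),)


def _covers(t: TreeNumber, branch: TreeNumber) -> bool:
    """Branch membership for selection: a bare category letter ("C", "D")
    covers every tree of that category; otherwise segment-wise in_branch."""
    if len(branch.segments) == 1 and len(branch.segments[0]) == 1:
        return t.segments[0][0] == branch.segments[0]
    return in_branch(t, branch)


def _tree_selected(
    t: TreeNumber,
    include: tuple[TreeNumber, ...],
    exclude: tuple[TreeNumber, ...] = (),
) -> bool:
    return any(_covers(t, b) for b in include) and not any(_covers(t, b) for b in exclude)


def _select(
    thesaurus: MeshThesaurus,
    supplementary: Iterable[MeshConcept],
    include: tuple[TreeNumber, ...],
    exclude: tuple[TreeNumber, ...],
) -> set[MeshConcept]:
    selected: set[MeshConcept] = set()
    selected_ids: set[str] = set()
    for c in thesaurus.concepts.values():
        if any(_tree_selected(t, include, exclude) for t in c.tree_numbers):
            selected.add(c)
            selected_ids.add(c.id)
    for s in supplementary:
        if s.mapped_to & selected_ids:
            selected.add(s)
    return selected


def select_disease_concepts(
    thesaurus: MeshThesaurus, supplementary: Iterable[MeshConcept] = ()
) -> set[MeshConcept]:
    """Descriptors with >=1 tree number in C or F03 outside the excluded
    branches, plus supplementary records mapping to a selected descriptor."""
    return _select(thesaurus, supplementary, DISEASE_BRANCHES, DISEASE_EXCLUDED_BRANCHES)


def select_chemical_concepts(
    thesaurus: MeshThesaurus, supplementary: Iterable[MeshConcept] = ()
) -> set[MeshConcept]:
    """Descriptors with >=1 tree number in category D, plus supplementary
    records mapping to one of them (kept under their own C-prefixed IDs)."""
    return _select(thesaurus, supplementary, CHEMICAL_BRANCHES, ())
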