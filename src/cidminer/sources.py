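"""Term -> MeSH-ID mappings harvested from a Wikipedia dump and the Disease Ontology.

Wikipedia article pages carrying a disease/symptom infobox with a MeSH
link-out contribute their title and every redirect pointing at them as
synonyms of that MeSH concept.  Infoboxes occasionally give a MeSH tree
number instead of an ID; those are resolved through the thesaurus tree index.
Redirects are a rich but non-semantic source ("History of acne" redirects to
acne without naming the disease), so both redirect titles and page titles are
screened against editable ignore lists.

The Disease Ontology contributes term names and synonyms for every stanza
with a ``MESH:`` cross-reference.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Iterator, Union

import obonet
from lxml import etree

from .mesh import MeshThesaurus, TreeNumber

logger = logging.getLogger(__name__)

__all__ = [
    "WikiPage",
    "MeshReference",
    "RefKind",
    "TermMapping",
    "stream_pages",
    "detect_medical_infobox",
    "resolve_reference",
    "harvest_wiki",
    "augment_by_title_match",
    "parse_disease_ontology",
    "load_ignore_list",
    "MEDICAL_INFOBOX_TEMPLATES",
    "MESH_PARAMETER_NAMES",
]

# Configurable sets; the source corpus only says "disease or symptom box"
# with "a link-out to MeSH".
MEDICAL_INFOBOX_TEMPLATES = {
    "infobox disease",
    "infobox medical condition",
    "infobox medical condition (new)",
    "infobox symptom",
}
MESH_PARAMETER_NAMES = ("MeshID", "MeshID2", "MeSH", "MeshNumber")


class RefKind(str, Enum):
    id = "id"
    tree_number = "tree_number"


@dataclass(frozen=True)
class MeshReference:
    kind: RefKind
    value: str


@dataclass
class WikiPage:
    title: str
    is_redirect: bool = False
    redirect_target: str | None = None
    wikitext: str = ""

    def __post_init__(self) -> None:
        if self.is_redirect and not self.redirect_target:
            raise ValueError("redirect page without a target")


@dataclass(frozen=True)
class TermMapping:
    surface_form: str
    mesh_id: str
    source: str  # wiki_title | wiki_redirect | wiki_title_match | disease_ontology


_REDIRECT_RE = re.compile(r"^\s*#REDIRECT\s*\[\[([^\]|]+)", re.IGNORECASE)


def _normalize_title(title: str) -> str:
    return re.sub(r"\s+", " ", title.replace("_", " ")).strip()


def stream_pages(dump: Union[str, bytes, IO[bytes]]) -> Iterator[WikiPage]:
    """Stream pages from a MediaWiki pages-articles XML dump in file order.

    Constant memory: each <page> element is cleared after it is yielded.
    Redirects are detected from the <redirect> element or from a leading
    ``#REDIRECT [[Target]]`` in the wikitext; section anchors are stripped
    from targets.
    """
    if isinstance(dump, (str, bytes)):
        dump = io.BytesIO(dump.encode() if isinstance(dump, str) else dump)
    for _event, elem in etree.iterparse(dump, events=("end",)):
        if etree.QName(elem).localname != "page":
            continue
        ns = etree.QName(elem).namespace
        p = f"{{{ns}}}" if ns else ""
        title_el = elem.find(f"{p}title")
        title = _normalize_title(title_el.text or "") if title_el is not None else ""
        redirect_el = elem.find(f"{p}redirect")
        text_el = elem.find(f"{p}revision/{p}text")
        wikitext = text_el.text or "" if text_el is not None else ""
        target: str | None = None
        if redirect_el is not None:
            target = redirect_el.get("title")
        else:
            m = _REDIRECT_RE.match(wikitext)
            if m:
                target = m.group(1)
        if target is not None:
            target = _normalize_title(target.split("#", 1)[0])
            yield WikiPage(title=title, is_redirect=True, redirect_target=target)
        else:
            yield WikiPage(title=title, wikitext=wikitext)
        elem.clear(keep_tail=True)


def _iter_templates(wikitext: str) -> Iterator[str]:
    """Yield top-level ``{{...}}`` template bodies (brace-depth scan)."""
    i, n = 0, len(wikitext)
    while i < n:
        start = wikitext.find("{{", i)
        if start < 0:
            return
        depth, j = 0, start
        while j < n - 1:
            pair = wikitext[j : j + 2]
            if pair == "{{":
                depth += 1
                j += 2
            elif pair == "}}":
                depth -= 1
                j += 2
                if depth == 0:
                    break
            else:
                j += 1
        if depth != 0:  # unbalanced: stop scanning
            return
        yield wikitext[start + 2 : j - 2]
        i = j


def _template_params(body: str) -> tuple[str, dict[str, str]]:
    """Split a template body into (name, top-level params)."""
    parts: list[str] = []
    depth, buf = 0, []
    for k in range(len(body)):
        ch = body[k]
        if body[k : k + 2] in ("{{", "[["):
            depth += 1
        elif body[k : k + 2] in ("}}", "]]"):
            depth -= 1
        if ch == "|" and depth <= 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    name = re.sub(r"\s+", " ", parts[0]).strip().lower()
    params: dict[str, str] = {}
    for part in parts[1:]:
        if "=" in part:
            key, _, val = part.partition("=")
            params.setdefault(key.strip(), val.strip())
    return name, params


_ID_SHAPE = re.compile(r"^[A-Z]\d+$")
_TREE_SHAPE = re.compile(r"^[A-Z]\d*(\.\d+)+$|^[A-Z]\d+[A-Za-z0-9.]*\.[A-Za-z0-9.]+$")


def detect_medical_infobox(wikitext: str) -> MeshReference | None:
    """Return the MeSH reference of the first medical infobox, if any.

    A reference is emitted only when the template name is in the configured
    medical-infobox set and it carries a MeSH parameter.  Value shape decides
    the kind: letter+digits -> id, dotted -> tree number.  Only the first
    populated MeSH parameter is used.
    """
    for body in _iter_templates(wikitext):
        name, params = _template_params(body)
        if name not in MEDICAL_INFOBOX_TEMPLATES:
            continue
        for key in MESH_PARAMETER_NAMES:
            value = params.get(key, "").strip()
            if not value:
                continue
            if _ID_SHAPE.match(value):
                return MeshReference(RefKind.id, value)
            if "." in value:
                return MeshReference(RefKind.tree_number, value)
        return None
    return None


def resolve_reference(ref: MeshReference, thesaurus: MeshThesaurus) -> str | None:
    """id references pass through; tree numbers resolve via the tree index."""
    if ref.kind == RefKind.id:
        return ref.value
    try:
        tn = TreeNumber.parse(ref.value)
    except ValueError:
        return None
    return thesaurus.tree_index.get(tn)


def harvest_wiki(
    pages: Iterable[WikiPage],
    thesaurus: MeshThesaurus,
    redirect_ignore: set[str] = frozenset(),
    title_ignore: set[str] = frozenset(),
) -> list[TermMapping]:
    """Map page titles and redirects of medical-infobox pages to MeSH IDs.

    Buffers (title -> id) for articles and (redirect -> target) pairs so that
    redirects may precede their target in the dump.
    """
    article_id: dict[str, str] = {}
    harvested_titles: list[str] = []
    redirects: list[tuple[str, str]] = []
    for page in pages:
        if page.is_redirect:
            redirects.append((page.title, page.redirect_target or ""))
            continue
        if page.title in title_ignore:
            continue
        ref = detect_medical_infobox(page.wikitext)
        if ref is None:
            continue
        mesh_id = resolve_reference(ref, thesaurus)
        if mesh_id is None:
            continue
        if page.title not in article_id:
            article_id[page.title] = mesh_id
            harvested_titles.append(page.title)

    mappings = [
        TermMapping(title, article_id[title], "wiki_title") for title in sorted(harvested_titles)
    ]
    for rtitle, target in sorted(redirects):
        if rtitle in redirect_ignore:
            continue
        mesh_id = article_id.get(target)
        if mesh_id is not None:
            mappings.append(TermMapping(rtitle, mesh_id, "wiki_redirect"))
    return mappings


def augment_by_title_match(
    pages: Iterable[WikiPage],
    base_lexicon,
    redirect_ignore: set[str] = frozenset(),
    already_harvested: set[str] = frozenset(),
) -> list[TermMapping]:
    """Link redirects of pages whose *title* is already a known disease term.

    ``base_lexicon`` must be built from MeSH + Disease Ontology only; pages
    already harvested through an infobox are skipped.  Only redirects are
    emitted (the title itself is in the lexicon by definition).
    """
    title_id: dict[str, str] = {}
    redirects: list[tuple[str, str]] = []
    for page in pages:
        if page.is_redirect:
            redirects.append((page.title, page.redirect_target or ""))
            continue
        if page.title in already_harvested or page.title in title_id:
            continue
        entry = base_lexicon.lookup(page.title)
        if entry is not None:
            title_id[page.title] = entry.concept_id
    out: list[TermMapping] = []
    for rtitle, target in sorted(redirects):
        if rtitle in redirect_ignore:
            continue
        mesh_id = title_id.get(target)
        if mesh_id is not None:
            out.append(TermMapping(rtitle, mesh_id, "wiki_title_match"))
    return out


_SYNONYM_RE = re.compile(r'^"(.*)"\s*(EXACT|RELATED|NARROW|BROAD)?')
_HARVESTED_SCOPES = {"EXACT", "RELATED", None}


def parse_disease_ontology(stream: Union[str, IO[str]]) -> list[TermMapping]:
    """Extract name + synonym mappings for every DO term with a MESH xref.

    EXACT and RELATED synonym scopes are harvested; obsolete terms are
    skipped.  Terms without a MeSH cross-reference contribute nothing.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream)
    mappings: list[TermMapping] = []
    for _node, data in graph.nodes(data=True):
        mesh_ids = [x.split(":", 1)[1] for x in data.get("xref", []) if x.startswith("MESH:")]
        if not mesh_ids:
            continue
        mesh_id = mesh_ids[0]
        name = data.get("name")
        if name:
            mappings.append(TermMapping(name, mesh_id, "disease_ontology"))
        for syn in data.get("synonym", []):
            m = _SYNONYM_RE.match(syn)
            if not m:
                logger.warning("unparseable synonym line skipped: %r", syn)
                continue
            if m.group(2) in _HARVESTED_SCOPES and m.group(1):
                mappings.append(TermMapping(m.group(1), mesh_id, "disease_ontology"))
    return mappings


def load_ignore_list(stream: Union[str, IO[str]]) -> set[str]:
    """One term per line; blank lines and '#' comments ignored."""
    if hasattr(stream, "read"):
        stream = stream.read()
    out: set[str] = set()
    for line in stream.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return out
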