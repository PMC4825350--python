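"""Assembly of the final matching lexicon from prioritized term sources.

Sources are merged in priority order (manual corrections first, then MeSH,
Disease Ontology, corpus-derived terms, Wikipedia); when the same surface form
occurs in several sources, the earliest source's MeSH ID wins.  At the point
of adding a term the builder also generates index-name uninversions
("Abnormality, Congenital" -> "Congenital Abnormality"), spelling variants
(tumour/tumor) and abbreviation splits ("X (AB)" -> "X" + "AB"); after
merging, modified terms ("infection" -> "disease") are added without ever
overwriting an existing entry.  A stop list removes surface forms that are
not diseases or are too ambiguous ("birth weight", "sterile", gene symbols).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from .sources import TermMapping

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "normalize_key",
    "merge_sources",
    "apply_stop_list",
    "uninvert",
    "spelling_variants",
    "modified_terms",
    "add_modified_terms",
    "load_corpus_terms",
    "expand_mapping",
    "build_lexicon",
    "mappings_from_concepts",
    "build_drug_induced_table",
    "write_lexicon_tsv",
    "read_lexicon_tsv",
    "DEFAULT_VARIANT_RULES",
    "DEFAULT_QUALIFIER_MARKERS",
    "DEFAULT_LIST_MARKERS",
    "DEFAULT_MODIFIED_SUBSTITUTIONS",
]

DEFAULT_QUALIFIER_MARKERS = (", with", ", without", ", in", ", during", ", following")
DEFAULT_LIST_MARKERS = (", or", ", and")
# Bidirectional within-word spelling rules (British/American).
DEFAULT_VARIANT_RULES = (
    ("our", "or"),
    ("or", "our"),
    ("ae", "e"),
    ("oe", "e"),
)
DEFAULT_MODIFIED_SUBSTITUTIONS = (
    ("infection", "disease"),
    ("cancer", "carcinoma"),
)


def normalize_key(surface: str) -> str:
    """Lexicon lookup key: lowercase + whitespace collapse, except that short
    forms (<=4 chars) and likely abbreviations (a word with >=2 uppercase)
    stay case-sensitive so that e.g. "AIDS" never folds onto "aids".

    Counting uppercase per word keeps ordinary Title-Case dictionary names
    ("Toy Carcinoma") case-folded while "MUMPS" or "ToyDisease" stay exact.
    """
    s = re.sub(r"\s+", " ", surface).strip()
    if len(s) <= 4 or any(sum(1 for c in w if c.isupper()) >= 2 for w in s.split(" ")):
        return s
    return s.lower()


@dataclass(frozen=True)
class LexiconEntry:
    surface_form: str
    concept_id: str
    entity_class: str = "disease"  # disease | chemical
    source: str = "mesh"  # manual | mesh | disease_ontology | corpus | wikipedia | generated
    generated_from: str | None = None

    def __post_init__(self) -> None:
        if not self.surface_form or not self.concept_id:
            raise ValueError("LexiconEntry needs surface_form and concept_id")


@dataclass
class Lexicon:
    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    stop_list: set[str] = field(default_factory=set)

    def lookup(self, surface: str) -> LexiconEntry | None:
        return self.entries.get(normalize_key(surface))

    def add(self, entry: LexiconEntry, overwrite: bool = False) -> bool:
        """Insert unless the key exists (first source wins) or is stop-listed."""
        key = normalize_key(entry.surface_form)
        if key in self.stop_list:
            return False
        if key in self.entries and not overwrite:
            if self.entries[key].concept_id != entry.concept_id:
                logger.debug(
                    "dropped %r -> %s from %s (kept %s from %s)",
                    entry.surface_form, entry.concept_id, entry.source,
                    self.entries[key].concept_id, self.entries[key].source,
                )
            return False
        self.entries[key] = entry
        return True

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())


# --- term transformations --------------------------------------------------

def uninvert(
    term: str,
    qualifier_markers: Sequence[str] = DEFAULT_QUALIFIER_MARKERS,
    list_markers: Sequence[str] = DEFAULT_LIST_MARKERS,
) -> str:
    """Rewrite an index-style inverted term into natural order.

    "Abnormality, Congenital" -> "Congenital Abnormality".  Terms containing a
    list marker (", or") are left unchanged; a trailing qualifier clause
    (", with ...") is detached, the remaining comma-separated parts are
    reversed and the qualifier re-appended without its comma.
    """
    if ", " not in term:
        return term
    if any(m in term for m in list_markers):
        return term
    head, qualifier = term, ""
    # longest marker first so ", with" never fires inside ", without"
    for marker in sorted(qualifier_markers, key=len, reverse=True):
        idx = term.find(marker)
        while idx != -1:
            after = term[idx + len(marker):]
            if after == "" or after.startswith(" "):
                head, qualifier = term[:idx], term[idx + 1 :].lstrip()
                break
            idx = term.find(marker, idx + 1)
        if qualifier:
            break
    parts = [p.strip() for p in head.split(", ")]
    # malformed inversions (empty parts, commas inside parts or qualifier)
    # are left alone — rewriting them would not terminate in a fixed point
    if any(not p or "," in p for p in parts) or "," in qualifier:
        return term
    out = " ".join(reversed(parts))
    if qualifier:
        out = f"{out} {qualifier}"
    return out


def _word_variants(word: str, rules: Sequence[tuple[str, str]]) -> set[str]:
    out: set[str] = set()
    for pat, repl in rules:
        start = 0
        while True:
            idx = word.find(pat, start)
            if idx < 0:
                break
            out.add(word[:idx] + repl + word[idx + len(pat):])
            start = idx + 1
    out.discard(word)
    return out


def spelling_variants(
    term: str, rule_table: Sequence[tuple[str, str]] = DEFAULT_VARIANT_RULES, cap: int = 64
) -> set[str]:
    """Spelling variants of ``term`` under within-word substring rules.

    One rule application per word, combined across words; the original term
    is excluded.  ``cap`` bounds the combinatorial product.
    """
    words = term.split(" ")
    choices = [[w, *sorted(_word_variants(w, rule_table))] for w in words]
    variants: set[str] = set()
    for combo in itertools.product(*choices):
        v = " ".join(combo)
        if v != term:
            variants.add(v)
            if len(variants) >= cap:
                return variants
    return variants


def modified_terms(
    term: str, substitutions: Sequence[tuple[str, str]] = DEFAULT_MODIFIED_SUBSTITUTIONS
) -> set[str]:
    """Whole-word single substitutions expected to be synonyms/refinements,
    e.g. "urinary tract infection" -> "urinary tract disease"."""
    out: set[str] = set()
    for src, dst in substitutions:
        pat = re.compile(rf"\b{re.escape(src)}\b")
        for m in pat.finditer(term):
            out.add(term[: m.start()] + dst + term[m.end():])
    out.discard(term)
    return out


_ABBREV_RE = re.compile(r"^(.*\S)\s+\(([A-Za-z0-9][A-Za-z0-9-]{0,7})\)$")


def expand_mapping(mapping: TermMapping) -> list[str]:
    """Surface forms contributed by one source mapping, primary form first.

    Splits "<name> (<ABBR>)" into name + abbreviation (they are two entities
    in running text), adds the uninverted form and spelling variants of each.
    """
    base: list[str] = []
    m = _ABBREV_RE.match(mapping.surface_form)
    if m:
        base.extend([m.group(1), m.group(2)])
    else:
        base.append(mapping.surface_form)
    forms: list[str] = []
    for term in base:
        for t in (term, uninvert(term)):
            if t not in forms:
                forms.append(t)
    for term in list(forms):
        for v in sorted(spelling_variants(term)):
            if v not in forms:
                forms.append(v)
    return forms


# --- merging ---------------------------------------------------------------

_SOURCE_TAGS = ("manual", "mesh", "disease_ontology", "corpus", "wikipedia", "generated")


def merge_sources(
    sources: Sequence[tuple[str, Iterable[TermMapping]]],
    entity_class: str = "disease",
    expand: bool = False,
    stop_list: set[str] | None = None,
) -> Lexicon:
    """Merge sources in priority order; the first source added wins a key.

    With ``expand=True`` each mapping also contributes its uninverted form,
    abbreviation split and spelling variants (marked generated_from).
    """
    lex = Lexicon(stop_list={normalize_key(s) for s in (stop_list or set())})
    for tag, mappings in sources:
        for mapping in mappings:
            surface = re.sub(r"\s+", " ", mapping.surface_form).strip()
            if not surface:
                continue
            forms = expand_mapping(replace(mapping, surface_form=surface)) if expand else [surface]
            for form in forms:
                lex.add(
                    LexiconEntry(
                        surface_form=form,
                        concept_id=mapping.mesh_id,
                        entity_class=entity_class,
                        source=tag,
                        generated_from=None if form == surface else surface,
                    )
                )
    return lex


def apply_stop_list(lexicon: Lexicon, stop_terms: set[str]) -> Lexicon:
    """Remove entries whose normalized form is stop-listed."""
    stop = {normalize_key(s) for s in stop_terms}
    kept = {k: v for k, v in lexicon.entries.items() if k not in stop}
    removed = len(lexicon.entries) - len(kept)
    if removed:
        logger.info("stop list removed %d entries", removed)
    return Lexicon(entries=kept, stop_list=lexicon.stop_list | stop)


def add_modified_terms(
    lexicon: Lexicon,
    substitutions: Sequence[tuple[str, str]] = DEFAULT_MODIFIED_SUBSTITUTIONS,
) -> Lexicon:
    """Add modified versions of existing terms; never overwrite an entry."""
    for entry in list(lexicon.entries.values()):
        for variant in sorted(modified_terms(entry.surface_form, substitutions)):
            lexicon.add(
                LexiconEntry(
                    surface_form=variant,
                    concept_id=entry.concept_id,
                    entity_class=entry.entity_class,
                    source="generated",
                    generated_from=entry.surface_form,
                )
            )
    return lexicon


def load_corpus_terms(corpus, entity_class: str = "disease") -> list[TermMapping]:
    """Distinct (gold surface form, MeSH ID) pairs from an annotated corpus.

    Unnormalized ("-1") and composite (multi-ID) annotations are skipped.
    """
    seen: set[tuple[str, str]] = set()
    out: list[TermMapping] = []
    for doc in corpus:
        for ann in doc.annotations:
            if ann.entity_class != entity_class:
                continue
            if len(ann.concept_ids) != 1:
                continue
            cid = ann.concept_ids[0]
            if cid == "-1":
                continue
            key = (ann.surface, cid)
            if key not in seen:
                seen.add(key)
                out.append(TermMapping(ann.surface, cid, "corpus"))
    return out


def mappings_from_concepts(concepts, source: str = "mesh") -> list[TermMapping]:
    """One TermMapping per (term, concept) of a MeSH concept set."""
    out: list[TermMapping] = []
    for c in sorted(concepts, key=lambda c: c.id):
        for term in sorted(c.terms):
            out.append(TermMapping(term, c.id, source))
    return out


def build_lexicon(
    sources: Sequence[tuple[str, Iterable[TermMapping]]],
    entity_class: str = "disease",
    stop_terms: set[str] | None = None,
    substitutions: Sequence[tuple[str, str]] = DEFAULT_MODIFIED_SUBSTITUTIONS,
) -> Lexicon:
    """Full build: priority merge with expansion, modified terms, stop list."""
    lex = merge_sources(sources, entity_class=entity_class, expand=True,
                        stop_list=stop_terms or set())
    lex = add_modified_terms(lex, substitutions)
    if stop_terms:
        lex = apply_stop_list(lex, stop_terms)
    return lex


_DRUG_INDUCED_RE = re.compile(r"drug[- ]induced", re.IGNORECASE)


def build_drug_induced_table(disease_concepts) -> dict[str, str]:
    """Map base-disease ID -> drug-induced-form ID.

    MeSH names the induced form like "Akathisia, Drug-Induced"; the base
    concept is the one named by the remainder after removing the marker.
    """
    by_name: dict[str, str] = {}
    for c in disease_concepts:
        by_name[normalize_key(c.preferred_name)] = c.id
        by_name.setdefault(normalize_key(uninvert(c.preferred_name)), c.id)
    table: dict[str, str] = {}
    for c in disease_concepts:
        if not _DRUG_INDUCED_RE.search(c.preferred_name):
            continue
        remainder = _DRUG_INDUCED_RE.sub(" ", c.preferred_name)
        remainder = re.sub(r"\s*,\s*", ", ", remainder)
        remainder = re.sub(r"(^[,\s]+|[,\s]+$)", "", remainder)
        remainder = re.sub(r"\s+", " ", remainder)
        for candidate in (remainder, uninvert(remainder)):
            base_id = by_name.get(normalize_key(candidate))
            if base_id and base_id != c.id:
                table[base_id] = c.id
                break
    return table


# --- serialization ---------------------------------------------------------

def write_lexicon_tsv(lexicon: Lexicon, stream: IO[str]) -> None:
    """surface_form, entity_class, concept_id, source — one entry per line."""
    for key in sorted(lexicon.entries):
        e = lexicon.entries[key]
        stream.write(f"{e.surface_form}\t{e.entity_class}\t{e.concept_id}\t{e.source}\n")


def read_lexicon_tsv(stream: IO[str]) -> Lexicon:
    lex = Lexicon()
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"lexicon TSV line {lineno}: expected 4 columns, got {len(parts)}")
        surface, entity_class, concept_id, source = parts
        lex.add(LexiconEntry(surface, concept_id, entity_class, source))
    return lex
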