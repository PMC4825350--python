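"""Pattern-based chemical-induced disease (CID) relation extraction.

The workflow per document: sentence splitting; POS-based grouping of
same-class mentions (entities not separated by a verb, preposition or
subordinating conjunction form one group); direction-aware regex patterns
over the text between/around a chemical group and a disease group; an
optional recall heuristic for documents where no pattern fired (all title
chemicals — or the most frequent abstract chemical — paired with all
diseases); optional precision filters blocking vague diseases and the
virus/inborn-genetic MeSH branches; and removal of redundant relationships
whose disease tree numbers are entirely refinements of another's.

Patterns avoid the most common negations through a guard lookbehind/lookahead
(``not associated with``, ``caused no``) and an ameliorative guard for the
temporal patterns (``improved after taking`` is not a CID).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .mesh import MeshThesaurus, TreeNumber, entirely_refines
from .ner import Mention

__all__ = [
    "Token",
    "Sentence",
    "EntityGroup",
    "Pattern",
    "CandidateRelation",
    "ExtractionConfig",
    "split_sentences",
    "rule_pos_tagger",
    "tag_sentence",
    "group_entities",
    "compile_pattern",
    "apply_patterns",
    "recall_heuristic",
    "filter_relations",
    "remove_redundant",
    "extract_document",
    "default_patterns",
    "make_config",
    "CONFIGURATION_NAMES",
    "DEFAULT_BLOCKED_IDS",
    "DEFAULT_BLOCKED_BRANCHES",
]


# --- sentences and POS -----------------------------------------------------

@dataclass(frozen=True)
class Token:
    surface: str
    pos: str  # VERB | ADP_SCONJ | OTHER
    start: int  # absolute character offset in the document


@dataclass
class Sentence:
    text: str
    offset: int
    tokens: list[Token] = field(default_factory=list)

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "etc", "al", "fig", "figs", "dr", "mr", "mrs", "st",
    "no", "ref", "refs", "approx", "ca", "cf", "resp", "wt", "vol",
}
_SENT_BREAK_RE = re.compile(r"[.!?]+(?=\s+[\"'(]?[A-Z0-9])")


def split_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence splitting with an abbreviation exception list.

    Sentences are non-overlapping, cover all non-whitespace text, and carry
    their character offset into the document.
    """
    if not text.strip():
        return []
    breaks: list[int] = []
    for m in _SENT_BREAK_RE.finditer(text):
        before = text[: m.start()]
        last_word = re.findall(r"[\w.]+$", before)
        token = (last_word[0].rstrip(".").lower() if last_word else "")
        if token in _ABBREVIATIONS:
            continue
        breaks.append(m.end())
    sentences: list[Sentence] = []
    prev = 0
    for b in breaks + [len(text)]:
        chunk = text[prev:b]
        stripped = chunk.strip()
        if stripped:
            offset = prev + chunk.index(stripped[0])
            sentences.append(Sentence(text=text[offset : offset + len(stripped)], offset=offset))
        prev = b
    return sentences


_VERBS = {
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "having", "do", "does", "did",
    "may", "might", "can", "could", "should", "would", "will", "shall", "must",
    "cause", "causes", "caused", "induce", "induces", "induced",
    "produce", "produces", "produced", "develop", "develops", "developed",
    "occur", "occurs", "occurred", "report", "reports", "reported",
    "show", "shows", "showed", "shown", "found", "observed", "led", "leads",
    "lead", "result", "results", "resulted", "improve", "improves", "improved",
    "remain", "remains", "remained", "follow", "follows", "followed",
    "include", "includes", "included", "suggest", "suggests", "suggested",
}
_ADP_SCONJ = {
    "in", "of", "on", "at", "by", "for", "with", "without", "during", "after",
    "before", "from", "to", "into", "onto", "over", "under", "between",
    "among", "within", "via", "upon", "per", "through", "throughout",
    "despite", "against", "because", "although", "though", "while", "since",
    "if", "unless", "when", "whereas", "that", "as", "until", "than",
    "toward", "towards", "about", "across", "along", "around", "behind",
    "beneath", "beside", "besides", "beyond", "concerning", "except",
    "following",
}


def rule_pos_tagger(surfaces: Sequence[str]) -> list[str]:
    """Deterministic coarse tagger: closed-class lexicon plus suffix rules.

    Serves as the default for the pluggable tagger contract (a callable from
    token surfaces to coarse tags VERB/ADP_SCONJ/OTHER), so no statistical
    model is required.
    """
    tags: list[str] = []
    for s in surfaces:
        low = s.lower()
        if low in _VERBS:
            tags.append("VERB")
        elif low in _ADP_SCONJ:
            tags.append("ADP_SCONJ")
        elif low.isalpha() and s.islower() and len(low) > 4 and low.endswith(("ed", "ing")):
            tags.append("VERB")
        else:
            tags.append("OTHER")
    return tags


_SENT_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")

Tagger = Callable[[Sequence[str]], list[str]]


def tag_sentence(sentence: Sentence, tagger: Tagger = rule_pos_tagger) -> Sentence:
    """Populate sentence tokens with coarse POS from the pluggable tagger."""
    matches = list(_SENT_TOKEN_RE.finditer(sentence.text))
    tags = tagger([m.group() for m in matches])
    sentence.tokens = [
        Token(m.group(), tag, sentence.offset + m.start())
        for m, tag in zip(matches, tags)
    ]
    return sentence


# --- entity grouping -------------------------------------------------------

@dataclass
class EntityGroup:
    mentions: list[Mention]

    @property
    def entity_class(self) -> str:
        return self.mentions[0].entity_class

    @property
    def start(self) -> int:
        return min(m.start for m in self.mentions)

    @property
    def end(self) -> int:
        return max(m.end for m in self.mentions)

    def concept_ids(self) -> list[str]:
        out: list[str] = []
        for m in self.mentions:
            for cid in m.concept_ids:
                if cid not in out:
                    out.append(cid)
        return out


def _blocking_token_between(sentence: Sentence, a_end: int, b_start: int) -> bool:
    return any(
        t.pos in ("VERB", "ADP_SCONJ")
        and t.start >= a_end
        and t.start + len(t.surface) <= b_start
        for t in sentence.tokens
    )


def group_entities(sentence: Sentence, mentions: list[Mention]) -> list[EntityGroup]:
    """Group same-class mentions not separated by a VERB/ADP_SCONJ token."""
    inside = sorted(
        (m for m in mentions if m.start >= sentence.offset and m.end <= sentence.end),
        key=lambda m: (m.start, m.end),
    )
    groups: list[EntityGroup] = []
    for cls in ("chemical", "disease"):
        current: list[Mention] = []
        for m in (x for x in inside if x.entity_class == cls):
            if current and not _blocking_token_between(sentence, current[-1].end, m.start):
                current.append(m)
            else:
                if current:
                    groups.append(EntityGroup(current))
                current = [m]
        if current:
            groups.append(EntityGroup(current))
    groups.sort(key=lambda g: (g.start, g.end))
    return groups


# --- patterns --------------------------------------------------------------

@dataclass
class Pattern:
    name: str
    direction: str  # chemical_first | disease_first
    regex: str | None  # None for the adjacency pattern
    scope: str = "between"  # between | full | adjacency
    enabled: bool = True
    precision: float | None = None  # reported precision on train+dev, metadata only

    def __post_init__(self) -> None:
        self._compiled = compile_pattern(self.regex) if self.regex else None

    def matches(self, sentence: Sentence, first: EntityGroup, second: EntityGroup) -> bool:
        rel = lambda pos: pos - sentence.offset
        if self.scope == "adjacency":
            return not _blocking_token_between(sentence, first.end, second.start)
        if self.scope == "between":
            inter = sentence.text[rel(first.end): rel(second.start)]
            return self._compiled.fullmatch(inter) is not None
        # full scope: the groups are replaced by class placeholders
        ph1 = "@CHEM@" if first.entity_class == "chemical" else "@DISEASE@"
        ph2 = "@CHEM@" if second.entity_class == "chemical" else "@DISEASE@"
        s = (
            sentence.text[: rel(first.start)] + ph1
            + sentence.text[rel(first.end): rel(second.start)] + ph2
            + sentence.text[rel(second.end):]
        )
        return self._compiled.search(s) is not None


def _split_top_level_alts(s: str) -> list[str]:
    parts, depth, buf = [], 0, []
    for ch in s:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if ch == "|" and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


_LOOKBEHIND_RE = re.compile(r"\(\?<!((?:[^()\\]|\\.|\([^()]*\))*)\)")


def compile_pattern(src: str) -> "re.Pattern[str]":
    """Compile a pattern regex, case-insensitively.

    Alternation inside a negative lookbehind is rewritten to a sequence of
    fixed-width lookbehinds (``(?<!not |[a-z])`` -> ``(?<!not )(?<![a-z])``,
    an exact equivalence) so patterns written with variable-width lookbehinds
    compile under the stdlib engine.  The character class ``[a-z]`` inside a
    lookbehind keeps its literal (case-sensitive) meaning.
    """
    def fix(m: "re.Match[str]") -> str:
        alts = _split_top_level_alts(m.group(1))
        return "".join(f"(?<!{a})" for a in alts)

    rewritten = _LOOKBEHIND_RE.sub(fix, src)
    rewritten = rewritten.replace("(?<![a-z])", "(?<!(?-i:[a-z]))")
    rewritten = rewritten.replace("(?<!not )", "(?<!(?-i:not ))")
    return re.compile(rewritten, re.IGNORECASE)


# The single regex printed in the source system's description covers
# "-associated", "associated with" and "cause[sd]"; "induce[sd]" and
# "produce[sd]" are extensions behind the same negation guards.
CAUSED_REGEX = (
    r".*(-associated|(?<!not |[a-z])"
    r"(associated with|cause[sd]|induce[sd]|produce[sd]))(?! no) .*"
)

# Temporal/ameliorative guard: "disease improved after taking chemical" is
# not a chemical-induced disease.
_AMELIORATIVE = (
    r"(?!.*\b(?:improv\w*|resolv\w*|recover\w*|remission|remitt\w*|"
    r"subsid\w*|ameliorat\w*|regress\w*|disappear\w*|heal\w*)\b)"
)


def default_patterns() -> list[Pattern]:
    """The shipped pattern library with the reported train+dev precisions."""
    return [
        # chemical precedes disease
        Pattern("chemical_caused", "chemical_first", CAUSED_REGEX, "between", True, 70.7),
        Pattern("chemical_disease_adjacency", "chemical_first", None, "adjacency", True, 62.1),
        Pattern("chemical_related_to", "chemical_first",
                r".*(?<!not |[a-z])related to(?! no) .*", "between", True, 80.0),
        Pattern("negative_effects_caused_by", "chemical_first",
                r".*\bnegative (?:side[- ])?effects? caused by @CHEM@.*@DISEASE@.*",
                "full", True, 66.7),
        Pattern("relationship_between_chem_and", "chemical_first",
                r".*\brelationships? between @CHEM@ and\b.*@DISEASE@.*", "full", True, 66.7),
        # disease precedes chemical
        Pattern("disease_caused_by", "disease_first",
                r".*(?<!not |[a-z])(?:cause[sd]|induced|produced|provoked|triggered) by(?! no) .*",
                "between", True, 72.47),
        Pattern("disease_after_or_during", "disease_first",
                _AMELIORATIVE + r".*\b(?:after|during)\b.*", "between", True, 58.70),
        Pattern("disease_after_or_while_taking", "disease_first",
                _AMELIORATIVE + r".*\b(?:after|while|on|upon) (?:taking|receiving|ingesting|"
                r"ingestion of|administration of|treatment with|therapy with)\b.*",
                "between", True, 67.00),
        Pattern("disease_in_person_taking", "disease_first",
                _AMELIORATIVE + r".*\bin (?:a |an |the )?(?:person|persons|people|patient|"
                r"patients|subject|subjects|child|children|woman|women|man|men|"
                r"individuals?|cases?)\b[^.;]*\b(?:taking|receiving|treated with|given|on)\b.*",
                "between", True, 81.80),
        Pattern("disease_effect_of", "disease_first",
                r".*\b(?:side |adverse )?effects? of\b.*", "between", True, 50.00),
        Pattern("disease_related_to", "disease_first",
                r".*(?<!not |[a-z])related to(?! no) .*", "between", True, 70.00),
        Pattern("disease_complications_of", "disease_first",
                r".*\bcomplications? (?:of|from)\b.*", "between", True, 70.60),
        Pattern("induction_of_by_or_with", "disease_first",
                r".*\binduction of @DISEASE@ (?:by|with)\b.*@CHEM@.*", "full", True, 66.70),
    ]


# --- relations -------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRelation:
    doc_id: str
    chemical_id: str
    disease_id: str
    chemical_surface: str
    disease_surface: str
    evidence: str
    origin: str  # pattern name or "heuristic"

    def __post_init__(self) -> None:
        if self.chemical_id == self.disease_id:
            raise ValueError("chemical and disease IDs must differ")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


def _pair_groups(
    sentence: Sentence,
    cg: EntityGroup,
    dg: EntityGroup,
    origin: str,
) -> list[CandidateRelation]:
    out: list[CandidateRelation] = []
    for cm in cg.mentions:
        for dm in dg.mentions:
            for cid in cm.concept_ids:
                for did in dm.concept_ids:
                    if cid == did or cid == "-1" or did == "-1":
                        continue
                    out.append(
                        CandidateRelation(
                            doc_id=cm.doc_id or dm.doc_id,
                            chemical_id=cid,
                            disease_id=did,
                            chemical_surface=cm.surface,
                            disease_surface=dm.surface,
                            evidence=sentence.text,
                            origin=origin,
                        )
                    )
    return out


def apply_patterns(
    sentence: Sentence,
    chem_groups: list[EntityGroup],
    disease_groups: list[EntityGroup],
    patterns: Sequence[Pattern],
) -> list[CandidateRelation]:
    """All (chemical group, disease group) pairs linked by an enabled pattern.

    On a match, every chemical in the chemical group is paired with every
    disease in the disease group.
    """
    relations: list[CandidateRelation] = []
    for pattern in patterns:
        if not pattern.enabled:
            continue
        for cg in chem_groups:
            for dg in disease_groups:
                if pattern.direction == "chemical_first":
                    first, second = cg, dg
                else:
                    first, second = dg, cg
                if first.end > second.start:
                    continue
                if pattern.matches(sentence, first, second):
                    relations.extend(_pair_groups(sentence, cg, dg, pattern.name))
    return relations


def recall_heuristic(
    doc,
    mentions: list[Mention],
    any_pattern_fired: bool,
) -> list[CandidateRelation]:
    """Cross-sentence fallback for documents where no pattern fired.

    All chemicals in the title — or, failing that, the single most frequently
    mentioned abstract chemical (ties broken by first occurrence) — are
    paired with every disease in the document.
    """
    if any_pattern_fired:
        return []
    title_len = len(doc.title)
    chems = [m for m in mentions if m.entity_class == "chemical"]
    diseases = [m for m in mentions if m.entity_class == "disease"]

    def ids_in_order(ms: Iterable[Mention]) -> list[tuple[str, str]]:
        seen, out = set(), []
        for m in sorted(ms, key=lambda x: x.start):
            for cid in m.concept_ids:
                if cid != "-1" and cid not in seen:
                    seen.add(cid)
                    out.append((cid, m.surface))
        return out

    title_chems = ids_in_order(m for m in chems if m.start < title_len)
    if title_chems:
        chosen = title_chems
    else:
        counts: dict[str, int] = {}
        first_pos: dict[str, int] = {}
        surface: dict[str, str] = {}
        for m in sorted(chems, key=lambda x: x.start):
            for cid in m.concept_ids:
                if cid == "-1":
                    continue
                counts[cid] = counts.get(cid, 0) + 1
                first_pos.setdefault(cid, m.start)
                surface.setdefault(cid, m.surface)
        if not counts:
            return []
        best = min(counts, key=lambda c: (-counts[c], first_pos[c]))
        chosen = [(best, surface[best])]

    out: list[CandidateRelation] = []
    seen_pairs: set[tuple[str, str]] = set()
    for cid, csurf in chosen:
        for did, dsurf in ids_in_order(diseases):
            if cid == did or (cid, did) in seen_pairs:
                continue
            seen_pairs.add((cid, did))
            out.append(
                CandidateRelation(
                    doc_id=getattr(doc, "doc_id", ""),
                    chemical_id=cid,
                    disease_id=did,
                    chemical_surface=csurf,
                    disease_surface=dsurf,
                    evidence=doc.title,
                    origin="heuristic",
                )
            )
    return out


# Diseases considered too vague to be useful relationship partners.
DEFAULT_BLOCKED_IDS = frozenset({"D064420", "D010300", "D003643", "D066126", "D020258"})
# Virus Diseases and Genetic Diseases, Inborn: unlikely to be chemical-induced.
DEFAULT_BLOCKED_BRANCHES = (TreeNumber.parse("C02"), TreeNumber.parse("C16.320"))


def filter_relations(
    relations: list[CandidateRelation],
    blocked_ids: frozenset[str] = DEFAULT_BLOCKED_IDS,
    blocked_branches: Sequence[TreeNumber] = DEFAULT_BLOCKED_BRANCHES,
    thesaurus: MeshThesaurus | None = None,
) -> list[CandidateRelation]:
    """Drop relations to blocked disease IDs or blocked MeSH branches.

    A disease absent from the thesaurus is kept (no tree evidence to block on).
    """
    from .mesh import in_branch

    kept: list[CandidateRelation] = []
    for rel in relations:
        if rel.disease_id in blocked_ids:
            continue
        if thesaurus is not None:
            concept = thesaurus.concepts.get(rel.disease_id)
            if concept is not None and any(
                in_branch(t, b) for t in concept.tree_numbers for b in blocked_branches
            ):
                continue
        kept.append(rel)
    return kept


def remove_redundant(
    relations: list[CandidateRelation],
    thesaurus: MeshThesaurus,
    direction: str = "drop_general",
) -> list[CandidateRelation]:
    """Remove redundant relationships within each chemical's relation set.

    When one disease's tree numbers are entirely (and strictly) refinements
    of another disease's, the more general relation is dropped under
    ``drop_general`` (keeping only the most specific relationships) or the
    more specific one under ``drop_specific``.  Diseases without tree
    numbers never participate.
    """
    if direction not in ("drop_general", "drop_specific"):
        raise ValueError(f"unknown redundancy direction {direction!r}")

    def trees(did: str):
        c = thesaurus.concepts.get(did)
        return c.tree_numbers if c is not None and c.tree_numbers else None

    by_chem: dict[tuple[str, str], set[str]] = {}
    for rel in relations:
        by_chem.setdefault((rel.doc_id, rel.chemical_id), set()).add(rel.disease_id)

    dropped: set[tuple[str, str, str]] = set()
    for (doc_id, chem), diseases in by_chem.items():
        ds = sorted(diseases)
        for a in ds:
            ta = trees(a)
            if ta is None:
                continue
            for b in ds:
                if a == b:
                    continue
                tb = trees(b)
                if tb is None:
                    continue
                # a strictly refines b
                if entirely_refines(ta, tb) and not entirely_refines(tb, ta):
                    victim = b if direction == "drop_general" else a
                    dropped.add((doc_id, chem, victim))
    return [r for r in relations if r.key not in dropped]


# --- orchestration ---------------------------------------------------------

CONFIGURATION_NAMES = ("patterns", "patterns+filters", "patterns+filters+heuristic")


@dataclass
class ExtractionConfig:
    patterns: list[Pattern] = field(default_factory=default_patterns)
    use_filters: bool = False
    use_heuristic: bool = False
    blocked_ids: frozenset[str] = DEFAULT_BLOCKED_IDS
    blocked_branches: Sequence[TreeNumber] = DEFAULT_BLOCKED_BRANCHES
    thesaurus: MeshThesaurus | None = None
    redundancy_direction: str = "drop_general"
    tagger: Tagger = rule_pos_tagger


def make_config(
    name: str,
    thesaurus: MeshThesaurus | None = None,
    patterns: list[Pattern] | None = None,
) -> ExtractionConfig:
    """One of the three named runs: ``patterns``, ``patterns+filters``,
    ``patterns+filters+heuristic``."""
    if name not in CONFIGURATION_NAMES:
        raise ValueError(f"unknown configuration {name!r}; expected one of {CONFIGURATION_NAMES}")
    return ExtractionConfig(
        patterns=patterns if patterns is not None else default_patterns(),
        use_filters="filters" in name,
        use_heuristic="heuristic" in name,
        thesaurus=thesaurus,
    )


def extract_document(doc, mentions: list[Mention], config: ExtractionConfig) -> list[CandidateRelation]:
    """Run the full extraction workflow on one title+abstract document.

    Pattern matching per sentence; the recall heuristic only if no pattern
    fired anywhere in the document; optional filters; redundancy removal;
    deduplication on (chemical ID, disease ID) keeping the first evidence.
    """
    text = doc.title + (" " + doc.abstract if doc.abstract else "")
    relations: list[CandidateRelation] = []
    for sentence in split_sentences(text):
        tag_sentence(sentence, config.tagger)
        groups = group_entities(sentence, mentions)
        chem_groups = [g for g in groups if g.entity_class == "chemical"]
        disease_groups = [g for g in groups if g.entity_class == "disease"]
        if chem_groups and disease_groups:
            relations.extend(apply_patterns(sentence, chem_groups, disease_groups, config.patterns))
    if config.use_heuristic and not relations:
        relations = recall_heuristic(doc, mentions, any_pattern_fired=False)
    if config.use_filters:
        relations = filter_relations(
            relations, config.blocked_ids, config.blocked_branches, config.thesaurus
        )
    if config.thesaurus is not None:
        relations = remove_redundant(relations, config.thesaurus, config.redundancy_direction)
    deduped: dict[tuple[str, str], CandidateRelation] = {}
    for rel in relations:
        deduped.setdefault((rel.chemical_id, rel.disease_id), rel)
    return list(deduped.values())
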