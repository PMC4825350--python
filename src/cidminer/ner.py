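"""Dictionary-based entity recognition with MeSH normalization.

Recognition is leftmost-longest dictionary lookup at word boundaries (a word
boundary is any transition to/from a letter-or-digit character, so hyphens
both join chemical names inside lexicon terms and still admit matches like
the chemical in "X-associated hepatitis").  A low level of spelling
correction (a single non-digit edit on spans of at least six characters, with
unambiguous normalization) recovers minor misspellings.  After recognition,
composite entities sharing a head word ("heart and lung disease") are
resolved to their reconstructed concepts, and whenever MeSH distinguishes a
drug-induced form of a disease that ID is preferred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from .lexicon import Lexicon, LexiconEntry, normalize_key, spelling_variants

__all__ = [
    "Mention",
    "MatchConfig",
    "find_mentions",
    "spell_tolerant_lookup",
    "detect_composites",
    "prefer_drug_induced",
    "normalize_chemical",
    "recognize",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_WORD_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class Mention:
    doc_id: str
    start: int
    end: int
    surface: str
    entity_class: str  # disease | chemical
    concept_ids: tuple[str, ...]
    provenance: str = "exact"  # exact | spell_corrected | composite | variant

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid mention span")
        if not self.concept_ids:
            raise ValueError("mention without concept IDs")


@dataclass
class MatchConfig:
    spelling_max_edits: int = 1
    spelling_min_length: int = 6

    def __post_init__(self) -> None:
        if self.spelling_max_edits not in (0, 1):
            raise ValueError("spelling_max_edits must be 0 or 1")


def _class_entries(lexicon: Lexicon, entity_class: str) -> dict[str, LexiconEntry]:
    return {
        k: e for k, e in lexicon.entries.items() if e.entity_class == entity_class
    }


def _one_nondigit_edit(a: str, b: str) -> bool:
    """True iff a and b differ by exactly one substitution/insertion/deletion
    not involving a digit."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1 or a == b:
        return False
    if la == lb:
        diffs = [i for i in range(la) if a[i] != b[i]]
        if len(diffs) != 1:
            return False
        i = diffs[0]
        return not (a[i].isdigit() or b[i].isdigit())
    if la > lb:
        a, b = b, a  # a is the shorter
        la, lb = lb, la
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:] and not b[i].isdigit()


def spell_tolerant_lookup(
    span: str, lexicon: Lexicon, config: MatchConfig, entity_class: str | None = None
) -> str | None:
    """ID of the unique lexicon term within one edit of ``span``.

    Guards: span length >= spelling_min_length, first character must agree,
    no edit may touch a digit; two candidate terms with distinct IDs mean
    the correction is ambiguous and nothing is returned.
    """
    if config.spelling_max_edits == 0 or len(span) < config.spelling_min_length:
        return None
    norm = normalize_key(span)
    hits: set[str] = set()
    for key, entry in lexicon.entries.items():
        if entity_class is not None and entry.entity_class != entity_class:
            continue
        if not key or key[0] != norm[0]:
            continue
        if _one_nondigit_edit(norm, key):
            hits.add(entry.concept_id)
    if len(hits) == 1:
        return next(iter(hits))
    return None


def find_mentions(
    text: str,
    lexicon: Lexicon,
    config: MatchConfig | None = None,
    doc_id: str = "",
    entity_classes: Sequence[str] = ("disease", "chemical"),
) -> list[Mention]:
    """Leftmost-longest non-overlapping dictionary matches per entity class.

    Matches start and end at word boundaries.  When no exact match starts at
    a token, spelling-tolerant lookup is attempted on the candidate spans
    (longest first) before moving on.
    """
    config = config or MatchConfig()
    tokens = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    mentions: list[Mention] = []
    for entity_class in entity_classes:
        entries = _class_entries(lexicon, entity_class)
        if not entries:
            continue
        max_tokens = max((len(_TOKEN_RE.findall(k)) for k in entries), default=1)
        sub = Lexicon(entries=entries)
        i = 0
        while i < len(tokens):
            matched_end_token = None
            hit: tuple[str, str] | None = None  # (concept_id, provenance)
            for j in range(min(i + max_tokens, len(tokens)) - 1, i - 1, -1):
                cand = text[tokens[i][0]: tokens[j][1]]
                entry = entries.get(normalize_key(cand))
                if entry is not None:
                    hit = (entry.concept_id, "exact")
                    matched_end_token = j
                    break
            if hit is None and config.spelling_max_edits > 0:
                for j in range(min(i + max_tokens, len(tokens)) - 1, i - 1, -1):
                    cand = text[tokens[i][0]: tokens[j][1]]
                    cid = spell_tolerant_lookup(cand, sub, config)
                    if cid is not None:
                        hit = (cid, "spell_corrected")
                        matched_end_token = j
                        break
            if hit is None:
                i += 1
                continue
            start, end = tokens[i][0], tokens[matched_end_token][1]
            mentions.append(
                Mention(
                    doc_id=doc_id,
                    start=start,
                    end=end,
                    surface=text[start:end],
                    entity_class=entity_class,
                    concept_ids=(hit[0],),
                    provenance=hit[1],
                )
            )
            i = matched_end_token + 1
    mentions.sort(key=lambda m: (m.start, m.end, m.entity_class))
    return mentions


_CONJUNCTIONS = {"and", "or"}


def detect_composites(text: str, mentions: list[Mention], lexicon: Lexicon) -> list[Mention]:
    """Resolve composite entities sharing a head word.

    For a multi-word recognized entity preceded by "and"/"or", the word
    before the conjunction is joined with the entity's last word; if the
    constructed term is in the lexicon, a mention covering the
    pre-conjunction word is added with the constructed term's ID.  Existing
    mentions are never altered.
    """
    words = [(m.start(), m.end(), m.group()) for m in _WORD_RE.finditer(text)]
    out = list(mentions)
    for mention in mentions:
        surface_words = mention.surface.split()
        if len(surface_words) < 2:
            continue
        before = [w for w in words if w[1] <= mention.start]
        if len(before) < 2:
            continue
        (cstart, cend, cword), (_, _, conj) = before[-2], before[-1]
        if conj.lower() not in _CONJUNCTIONS:
            continue
        core = re.sub(r"^[^A-Za-z0-9]+|[^A-Za-z0-9]+$", "", cword)
        if not core:
            continue
        cstart += cword.find(core)
        cend = cstart + len(core)
        constructed = f"{core} {surface_words[-1]}"
        entry = lexicon.lookup(constructed)
        if entry is None or entry.entity_class != mention.entity_class:
            continue
        if any(
            m.entity_class == mention.entity_class and m.start < cend and cstart < m.end
            for m in out
        ):
            continue
        out.append(
            Mention(
                doc_id=mention.doc_id,
                start=cstart,
                end=cend,
                surface=text[cstart:cend],
                entity_class=mention.entity_class,
                concept_ids=(entry.concept_id,),
                provenance="composite",
            )
        )
    out.sort(key=lambda m: (m.start, m.end, m.entity_class))
    return out


def prefer_drug_induced(
    mentions: list[Mention], preference_table: dict[str, str]
) -> list[Mention]:
    """Rewrite disease IDs to their drug-induced MeSH form where one exists."""
    out: list[Mention] = []
    for m in mentions:
        if m.entity_class == "disease" and any(c in preference_table for c in m.concept_ids):
            out.append(
                replace(m, concept_ids=tuple(preference_table.get(c, c) for c in m.concept_ids))
            )
        else:
            out.append(m)
    return out


def normalize_chemical(surface: str, chem_lexicon: Lexicon) -> str | None:
    """Resolve a recognized chemical name to a MeSH ID, trying variants.

    Order: exact; strip trailing "s"/"es"; add plural "s"/"es"; spelling
    variant rules.  First hit wins.
    """
    candidates = [surface]
    if surface.endswith("es"):
        candidates.append(surface[:-2])
    if surface.endswith("s"):
        candidates.append(surface[:-1])
    candidates.extend([surface + "s", surface + "es"])
    candidates.extend(sorted(spelling_variants(surface)))
    for cand in candidates:
        entry = chem_lexicon.lookup(cand)
        if entry is not None and entry.entity_class == "chemical":
            return entry.concept_id
    return None


def recognize(
    text: str,
    lexicon: Lexicon,
    config: MatchConfig | None = None,
    doc_id: str = "",
    drug_induced_table: dict[str, str] | None = None,
) -> list[Mention]:
    """Full recognition pass: dictionary matching, composite resolution and
    the drug-induced ID preference."""
    mentions = find_mentions(text, lexicon, config, doc_id=doc_id)
    mentions = detect_composites(text, mentions, lexicon)
    if drug_induced_table:
        mentions = prefer_drug_induced(mentions, drug_induced_table)
    return mentions
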