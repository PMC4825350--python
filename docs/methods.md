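# Methods

## Scope and data model

The package mines chemical-induced disease (CID) relationships from
title+abstract documents. Its in-memory objects mirror the BC5CDR/PubTator
conventions: a document is `title + " " + abstract` with 0-based half-open
character offsets; a mention carries one or more MeSH concept IDs; a relation
is a (chemical ID, disease ID) pair per document with an evidence passage.
All evaluation is document-level over concept IDs, not spans (span-level
diagnostics can be derived from the mention offsets, which are always exact).

## Lexicon construction

Sources are merged in a fixed priority order — manual corrections, MeSH,
Disease Ontology, corpus-derived gold terms, Wikipedia — and the earliest
source to contribute a (normalized) surface form fixes its ID. The merge is
therefore deterministic under permutation *within* a source and sensitive
only to source order, which is the point: a curated one-line correction
("heart disease") beats a misleading Wikipedia redirect (to cardiovascular
disease) without touching the bulk sources.

Key normalization folds case and collapses whitespace, **except** for forms
of length ≤ 4 or containing a word with ≥ 2 uppercase letters, which are
stored case-sensitively. Short forms and acronyms ("AIDS", "MUMPS",
"ToyDisease") are the dominant source of false matches in this kind of
gazetteer; keeping them exact means "aids" in running text never hits the
syndrome. Counting uppercase per word (not per form) keeps ordinary
Title-Case dictionary names ("Toy Carcinoma") case-folded and therefore
matchable in lowercase text.

Term expansion at insertion time:

* **Uninversion** rewrites index-order names by splitting on ", " and
  reversing ("Abnormality, Congenital" → "Congenital Abnormality"). Terms
  containing a list marker (", or", ", and") are left alone; a trailing
  qualifier clause (", with …", ", without …", ", in …", ", during …",
  ", following …") is detached first and re-appended without its comma.
  Degenerate inputs (empty comma parts, commas inside parts or the
  qualifier) are returned unchanged — rewriting them has no fixed point, and
  idempotence of the rewrite is a tested invariant.
* **Spelling variants** apply bidirectional within-word substring rules
  (our↔or, ae→e, oe→e), one application per word, combined across words with
  a 64-variant cap. The expansion direction of a rule can produce nonsense
  variants ("Abnourmality"); these are tolerated because variants never
  overwrite an existing entry and nonsense keys do not occur in text.
* **Abbreviation split**: "<name> (<ABBR>)" becomes two entries, since name
  and abbreviation surface as two separate entities in running text.
* **Modified terms** (infection→disease, cancer→carcinoma) are generated
  after the merge with `generated` provenance and never displace an entry.

The stop list is applied both during insertion and as a final sweep, so no
generated form can resurrect a stopped term.

The drug-induced preference table is scanned from the selected disease
concepts: a concept whose preferred name contains "Drug-Induced" is paired
with the concept named by the remainder (checked both verbatim and
uninverted), giving a base-ID → induced-ID map applied to every disease
mention after recognition.

## Recognition

Matching is leftmost-longest per entity class at word boundaries, where a
boundary is any transition to or from a letter-or-digit character. This
definition lets hyphens both live inside lexicon terms ("drug-induced
hepatitis") and delimit matches ("aspirin-associated …" still yields the
chemical). The scanner enumerates candidate spans from each token start,
longest first, and is property-tested for exact agreement with a brute-force
oracle that tries every dictionary term at every boundary pair.

Spelling tolerance is deliberately conservative: only when no exact match
starts at a position, only for spans of ≥ 6 characters, at most one edit,
the first character must agree, no edit may involve a digit (gene1 ≠ gene2),
and a correction reachable from two distinct concept IDs is refused.
Disabling correction always yields a subset of the mentions found with it —
a tested invariant.

Composite resolution implements the conjunction-sharing rule: for a
multi-word recognized entity preceded by "and"/"or", the token before the
conjunction is joined with the entity's head word; if the reconstructed term
is in the lexicon a new mention covering only the pre-conjunction token is
added. One conjunction hop is attempted; hyphenated tokens count as single
words. Existing mentions are never modified.

Chemical normalization tries, in order: exact lookup, stripped "es"/"s"
plural, added "s"/"es", spelling-variant rules; first hit wins.

## Relation extraction

Sentences come from a rule-based splitter (terminal punctuation followed by
whitespace and an uppercase/digit, with an abbreviation exception list).
POS tagging is a pluggable contract — any callable from token surfaces to
coarse tags {VERB, ADP_SCONJ, OTHER}; the default is a deterministic
closed-class lexicon plus a suffix rule (lowercase, length > 4, ending
-ed/-ing), so no model download is required and test behavior is exactly
reproducible. Grouping merges same-class mentions with no VERB/ADP_SCONJ
token strictly between them: conjunctions keep "Hypohidrosis and
hyperthermia" together while "during" separates them from "topiramate".

Patterns are direction-aware (chemical-first vs disease-first) and carry the
precision estimate measured on the original task's training+development data
as metadata. Three scopes exist: `between` (regex full-matched against the
inter-group text — this is where the caused-pattern's printed form applies),
`full` (regex searched against the sentence with the two groups replaced by
`@CHEM@`/`@DISEASE@` placeholders, used for "relationship between X and Y",
"induction of D by C", "negative effects caused by C"), and `adjacency`
(chemical group immediately before a disease group with no VERB/ADP_SCONJ
between). On a match, every chemical in the chemical group pairs with every
disease in the disease group.

Numerical/regex choices: patterns compile case-insensitively, except that
the literal `[a-z]` inside the printed lookbehind keeps its case-sensitive
meaning (it is a within-word guard, e.g. it stops "cause" matching inside
"because"); `(?<!not )` is likewise kept literal. Alternations inside a
negative lookbehind are rewritten to an equivalent sequence of fixed-width
lookbehinds (`(?<!not |[a-z])` → `(?<!not )(?<![a-z])`) so the stdlib engine
accepts the published pattern verbatim. The temporal patterns (after/during,
after-taking, in-person-taking) carry an ameliorative guard rejecting
improvement/remission wording, so "hepatitis improved after taking X" is not
extracted. The caused-pattern ships with "induce[sd]"/"produce[sd]" as
clearly marked extensions behind the same guards.

The recall heuristic runs only when no pattern fired in the whole document:
all distinct title chemicals — or, failing that, the single most frequent
abstract chemical, ties broken by earliest occurrence — are paired with all
diseases in the document. Filters drop relations to five over-vague disease
IDs (D064420, D010300, D003643, D066126, D020258) and to diseases with any
tree number under C02 (virus diseases) or C16.320 (inborn genetic diseases);
a disease absent from the thesaurus is kept, since there is no tree evidence
against it. Redundancy removal then deletes, within each chemical's relation
set, the more general of two diseases when one's tree numbers are entirely
and strictly refinements of the other's (`drop_general`, the default — the
gold standard keeps only the most specific relationships; the opposite
`drop_specific` reading is available as a switch because the rule's prose
admits both). Mutual refinement (identical tree sets) drops neither.
Strictness makes a single pass over all pairs a fixed point, and both
filtering and redundancy removal are idempotent and order-insensitive —
tested invariants.

## Fixtures and what they show

The toy thesaurus (24 descriptors, 3 supplementary records) encodes each
selection edge case: excluded-branch-only concepts, a multi-axial concept
rescued by a surviving tree, an F03 concept, nested carcinoma trees for
redundancy, a drug-induced/base pair, the five filter-blocked IDs, and the
worked-example trio. The Wikipedia dump covers ID and tree-number infobox
link-outs, redirects, ignore-list hits and title-match augmentation; its
expected 7-mapping harvest is committed as a golden set.

The planted corpus generator emulates the *structural* conditions of the
task — one to three relation-bearing sentences per abstract drawn from
per-pattern templates, 20% of negatable sentences rendered with the guard
phrases ("caused no", "was not associated with", "improved during",
"resolved after taking") at the defaults, entities drawn from the toy
thesaurus with pairwise non-nested disease trees so redundancy removal never
trims a planted pair. It does **not** emulate real abstracts' vocabulary
breadth, annotation ambiguity, cross-sentence relations, or curator
disagreement: perfect recovery on the planted corpus demonstrates that the
machinery (recognition, grouping, every shipped pattern, the negation and
ameliorative guards, scoring) is internally correct, not that corpus-level
F1 on BC5CDR would be reproduced — that requires the external corpus, full
MeSH and a Wikipedia dump, which the same CLI accepts unchanged.

Problem sizes throughout (100-document corpora, 200 randomized matcher
fixtures, 500 random tree-number sets) were chosen as the package's own
defaults so the whole suite runs in seconds while still exercising every
branch of the algorithms.

## Known limitations

* No protein/gene recognition: "tumor necrosis factor" can yield spurious
  disease hits, a known error mode of dictionary-only recognition.
* The grammar-based systematic chemical-name recognizer of the original
  system is proprietary; this package uses its dictionary recognizer for
  chemicals and exposes the mention contract so an external recognizer can
  be plugged in.
* Ameliorative phrasing is handled by guards, not understanding; inverted
  meanings like "remission of X under Y" can still slip through.
* Redirect chains are followed one hop; qualifier (subheading) records and
  MeSH pharmacological-action lists are out of scope.
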