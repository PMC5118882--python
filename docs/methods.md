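# Methods

## Overview

`cdeharvest` operationalizes a workflow that is usually carried out by
hand in multi-partner trial consortia: pooling CRF metadata from many
sponsors, agreeing on a deduplicated element list per form domain, and
asking hospital sites which of those elements their EHR can deliver.
The package replaces the two human steps — expert deduplication review
and consensus domain allocation — with deterministic algorithms plus
override tables, so the whole analysis is reproducible and its
automatic parts can be scored against ground truth.

## Data model

A **study set** holds trials, forms and items. Trial metadata is
mandatory and validated at ingestion: disease area from a closed
seven-area enum, planned enrollment ≥ 1 (it is the ranking weight, so
trials without it are rejected rather than defaulted), site count ≥ 1.
Repeating and unscheduled forms are ingested once with a `repeating`
flag; repetition never multiplies element counts, because the analysis
counts forms, not form instances. Labels are taken from the ODM item
Question (preferred-language TranslatedText, falling back to any
question text, then to the item Name); `SDSVarName` populates the CDISC
variable name. Encoding is fixed to UTF-8; other encodings must be
declared in the tabular dialect config.

## Label cleaning

Cleaning applies, in order: HTML entity unescaping, tag stripping,
inline-CSS removal, whitespace collapsing, and stripping of a single
trailing parenthesized/bracketed token **only when** it matches the
unit lexicon (so "Temperature (axillary)" keeps its qualifier while
"Heart Rate (bpm)" loses its unit into `removed_units`). The shipped
lexicon covers common UCUM-style print units and is extensible; case is
preserved — folding happens inside matching. Labels that clean to the
empty string are excluded from clustering and counted.

## Matching and clustering

Two cleaned labels match when, in order of precedence:

1. both carry CDISC variable names: equal (case-insensitive) names
   match, unequal names **veto** regardless of text similarity;
2. case-folded texts are equal;
3. Jaro–Winkler ≥ `jw_threshold` (default 0.90, prefix weight 0.1) and
   Levenshtein ≤ min(`lev_max` = 3, ⌊`lev_len_ratio` = 0.25 ·
   max(|a|,|b|)⌋) and, if `require_phonetic_agreement` (default off),
   equal Metaphone codes.

The length-scaled edit budget stops short labels (AST/ALT) from
merging on a single edit while allowing three edits between long ones.
All thresholds live in a `SimilarityConfig` that is serialized with
every run.

Clustering is single-linkage agglomeration implemented with union-find
over *representatives* (distinct case-folded text + variable-name
pairs), with two candidate-pair generators: a pass over shared variable
names, and pairwise comparison within blocks keyed by the first
Metaphone character. Blocking is a deliberate completeness trade-off:
fuzzy matches whose variants start with different phonemes are missed.
The hard-key veto is enforced transitively — a union that would bring
two distinct non-null variable names into one cluster is skipped and
logged. Determinism: items are sorted on (case-folded text, trial,
form, item) before any pairwise work and cluster ids are assigned from
sorted canonical labels, so output is invariant under input
permutation. The canonical label is the modal variant's cleaned text,
ties broken by shortest then lexicographically smallest; in the
intended workflow expert review then fixes whatever the election got
wrong, via the override table (merge / split / rename / remove /
recategorize, applied in file order, locking affected clusters). A
warning fires when one cluster exceeds 25 % of a corpus of at least 20
items, which usually means the thresholds are too loose for the
vocabulary at hand.

The three string metrics are implemented in the package itself
(`textmetrics`): classic two-row dynamic-programming Levenshtein;
Jaro similarity with the standard window ⌊max(|a|,|b|)/2⌋−1 and the
Winkler prefix boost `j + L·p·(1−j)` (L ≤ 4, p ≤ 0.25, applied
unconditionally, which keeps the function symmetric and bounded);
original Metaphone (not Double Metaphone) over the alphabetic content
of the whole label, so multi-word labels encode as one run. The test
suite checks all three against independent implementations
(`edlib` for Levenshtein; clean-room reimplementations for the other
two) on 10⁴ random pairs, plus the metric axioms for Levenshtein.

## Domain mapping

The 14-domain dictionary mirrors the consensus domain list of this
analysis type (Medical History … Tumor response), including the custom
code for Disease Characteristics and the codeless Surgery domain. The
keyword rules are a surrogate for expert allocation — first matching
rule in dictionary order wins on the cleaned form name — and the
per-form override table is authoritative. Each form receives exactly
one domain; multi-topic forms are not split. Forms matching nothing are
reported under `unassigned` so form counts are conserved.

## Inventory

Domains whose forms appear no more than once are removed before
ranking. The singleton rule is interpreted corpus-wide (a domain with
two forms in one trial survives); `min_forms` exposes the alternative.
The weighted score of an element is the sum of planned enrollments of
the distinct trials containing it; `weight="per_form"` instead counts
each form occurrence, for corpora where within-trial repetition should
matter. Both `n_trials` and `n_form_occurrences` are always emitted.
Sorting is total (score desc, trial count desc, label asc, id asc), so
ranks are dense 1..N and reproducible. An element whose occurrences
span several domains yields one row per domain with per-domain counts,
logged.

Prior-inventory comparison matches by UMLS CUI when both sides carry
one, else by case-folded label; the partition into identical/new is
exhaustive and duplicate prior keys are fatal. Semantic codes come from
a static mapping table; codes are validated syntactically
(CUI `C` + 7 digits, SNOMED all digits) but never asserted as medical
truth.

## EHR coverage

Frequency of documentation is `100 · n_values / n_patients` for the
reference year, rounded **half-up** to one decimal to match the printed
convention (e.g. 9574/31493 → 30.4 %); values above 100 % are
legitimate (multiple measurements per patient). Sites that may not
export counts contribute availability flags only; a bare `unknown`
degrades to not-available with a warning, and a not-available row never
carries positive counts (rows violating that are rejected and counted).
Export keys resolve against the inventory by cde id, then semantic
code, then case-folded label; ambiguous keys are an error rather than a
guess. The heat map is a complete element × site grid (missing cells
default to not-available), rows ordered by number of covering sites,
then mean frequency, then label — a total order, so the matrix is
invariant under input file order. The SAE view is the same matrix
restricted to the adverse-event domain.

## Synthetic corpus

The generator emulates the corpus shape the analysis was designed for:
23 trials across 7 disease areas with fixed per-area form totals
(1086 forms overall), four-digit planned enrollments, 200+ site counts,
and a ~280-name per-domain vocabulary including the canonical SAE item
set (seriousness, action taken, autopsy report, date of death, …),
which is forced into every adverse-event form. Form names embed their
domain's display name plus a visit qualifier, so keyword mapping can be
scored against the recorded true domains. Noise is applied per item
occurrence with fixed draw order (typo, case, unit suffix, markup wrap)
from a single seeded RNG stream; defaults are p_typo = 0.05 with 1–2
edits, p_case = 0.10, p_unit = 0.15, p_markup = 0.10, and CDISC
variable names present with p = 0.30. Injected typos record their
*recomputed* edit distance, since random edits can cancel. Vocabulary
names are deliberately kept several edits apart so that default-level
noise cannot turn one true element into another within the matching
thresholds; real corpora offer no such guarantee, which is exactly why
the override table exists.

What the generator does **not** emulate: multilingual labels,
free-text items, semantically overlapping distinct elements
(systolic vs diastolic pressure are kept lexically separable),
form-level element correlation beyond domains, and patient-level data.
Passing recovery tests therefore demonstrate correctness of the
machinery under the stated noise model, not expected accuracy on an
arbitrary real corpus.

Site exports are generated per element with domain-specific
availability probabilities (demographics and laboratory lead; the AE
domain is forced sparse at more than half of the sites, except date of
death), two of seven sites as availability-only, and the reference
worked example (9 574 values / 31 493 patients for "Bilirubin, total"
at site 1) pinned so the frequency statistic's printed example is
reproduced end to end.

## Problem sizes and runtime

The default test and acceptance runs use the full-shape corpus
(23 trials, 1086 forms, ≈13 000 items), which clusters in about one
second thanks to representative deduplication and Metaphone blocking;
unit tests use a two-area ~30-form corpus. The acceptance script runs
the complete pipeline twice (noisy and noise-free) in a few seconds.

## Known limitations

- Blocking misses fuzzy merges across different initial phonemes; the
  variable-name pass recovers some of them.
- Canonical-name election is frequency-based, not expert-informed;
  overrides are the intended correction channel.
- The corpus-wide singleton-domain rule and the per-trial weighting
  formula are documented interpretations of an under-specified manual
  procedure; both have config alternatives.
- Coverage matching trusts export counts as given; it does not
  deduplicate repeated measurements per patient.
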