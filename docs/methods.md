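# Methods

This note documents the models, conventions and numerical choices behind
lexikit, in the order the build pipeline applies them.

## Input model and cleaning

The unit of input is a per-category frequency list: one UTF-8 line per
word type, `form<whitespace>count`, with one file per grammatical category
(`adj, adv, gram, nom, num, ver, prop`). The pipeline:

1. lower-cases every form and merges case variants within a category by
   **summing** their counts. Summing (rather than keeping one variant's
   count) conserves the token total, which downstream per-million and Zipf
   columns divide by; the merge count is reported.
2. removes forms longer than 30 characters (they are of no
   stimulus-selection interest and are typically tokenization debris);
3. removes digit-containing forms, except the single digits 0–9 and the
   ordinals 1º–9º / 1ª–9ª (also accepted with the degree sign °, a common
   mojibake of º), and only when these occur as adjectives, nouns or
   numerals. "Contains a digit" is the numeric test; it is deliberately
   broad (it removes `r2d2`, years, percentages) with the explicit
   whitelist as the only exception.

Cleaning counters satisfy `kept + removals = input − merges` and are
checked by tests.

## Lexicon assembly and ordering

Entries are sorted by descending raw frequency, then by orthography under
a reproducible collation: Latin letters a–z first (accented letters
collate with their base letter), then digits 0–9, then the hyphen, then
any other character, with the raw code point as the final per-character
tie-break. Entries identical in frequency and orthography (homographs with
equal counts) are ordered by category code in the conventional category
order — a package choice needed to make the sort total. The row number in
this order is the `id` column, so rebuilding from shuffled input yields a
byte-identical lexicon.

The `random` column draws one uniform [0,1) per entry from a single seeded
generator (NumPy PCG64) in id order, rounded half-even to 8 decimals. It
exists for stimulus-list randomization; the seed is a required argument so
lists are reproducible.

## Frequency transforms

For raw count `f` and corpus token total `N`:

- `ortho_freq/M = f / N × 10⁶`
- `log10_ortho_freq = log10(f)` — defined only for `f ≥ 1`; zero counts are
  rejected rather than smoothed, because the lexicon only carries attested
  words and any smoothing constant would leak into the Zipf scale.
- `zipf_scale = log10(f / N × 10⁶) + 3`, the corpus-size-independent 1–7
  scale. The identity `zipf_scale − log10_ortho_freq = 9 − log10(N)` holds
  per lexicon and is property-tested.
- `zipf_rank`: dense ranking by descending frequency — the highest distinct
  frequency is rank 1, each next distinct frequency increments the rank by
  one, ties share a rank. Dense (not competition) ranking is the only
  reading consistent with "words with the same frequency share a rank"
  while "the second most frequent word has rank 2". Ranks are computed over
  lexicon rows, not homograph-collapsed forms, because the column lives on
  each row.

The stored columns round per-million, log and Zipf values to 4 decimals,
matching conventional publication precision. A documented quirk of the
published worked example: the per-million value for a count of 397
reproduces at the pre-cleaning corpus total (31,377,670 tokens), while the
Zipf value reproduces at the post-cleaning total (30,705,945). Both are
reachable through the `total` argument; the package takes no position on
which the original database used.

## Orthographic structure

`nb_letters` counts **every** character — hyphens, accented letters,
digits. This is forced by the window identities: the bigram decomposition
of a word of L characters over the `#`-bounded string has exactly L+1
windows and the trigram decomposition L windows, and the CVCV alphabet
reserves a class (P) for in-word punctuation, so punctuation must count.

CVCV coding maps each character to one of six classes: V for plain vowels,
C for consonants (ç included), A for accented vowels, N for digits, P for
hyphen/apostrophe, S for anything else (º, ª, …). The default table is a
plain dict and can be replaced wholesale; a custom table must cover every
character it meets, while the default falls back to S.

Decomposition always slides over the bounded string, so a 1-letter word
has two bigrams (`#a`, `a#`) and one trigram (`#a#`) — the degenerate case
continues the general formula rather than special-casing short words.

## Corpus-relative measures

All three form-based measures run on the set of **distinct orthographic
forms pooled across categories**: a homograph is the same letter string,
hence not its own neighbor and not a disambiguating competitor.

- **Uniqueness point**: smallest prefix length shared with no other form.
  Because the longest common prefix with any other form is attained at an
  adjacent form in sorted order, one sorted pass computes all points in
  O(total characters). A form that is a prefix of another (casa/casas) has
  no disambiguating position and gets `nb_letters + 1`, keeping the column
  numeric and order-preserving.
- **Coltheart's N**: same-length forms at Hamming distance 1, computed per
  length group with vectorized character-matrix comparisons (blocked to
  bound memory).
- **OLD20**: mean unit-cost Levenshtein distance to the 20 nearest other
  forms (all of them when fewer than 20 exist), ties at the 20th distance
  resolved on the distance multiset. Distances come from edlib; the batch
  computation scans candidates in increasing length difference and stops
  when the length bound (edit distance ≥ |Δlength|) can no longer improve
  the current 20th-smallest distance. The test suite checks the batch path
  against an independent pure-Python all-pairs Wagner–Fischer oracle.
- **Homographs**: `nb_homogr` counts the form's category memberships
  including its own (a form in adj/nom/ver reports 3), with the codes
  listed in conventional category order.

The published full-corpus reference values for these columns (uniqueness
point 8, N = 2, OLD20 = 1.75 for the demo word) depend on the complete
source corpus and cannot be reproduced from the shipped demo lexicon;
tests therefore check these measures against oracles on random lexicons
instead.

## Positional n-gram tables

Tables count **word types** per (category, 1-based position, n-gram) —
raw frequency is ignored, and the same n-gram at two positions of one word
counts at each. Position-collapsed, category-collapsed and fully collapsed
marginals are derived lazily. The per-word `bigram_freq`/`trigram_freq`
columns sum the position- and category-specific counts of the word's own
windows; which marginal the original databases summed is not documented,
so both collapse switches are exposed and the positional/categorial sum is
the default (it is the most specific and the one the pseudoword engine
needs).

## Search semantics

- `_` matches **exactly one** character. The published wildcard table says
  "one or more", but its own printed result set (4-letter words only) is
  inconsistent with that reading; the single-character semantics reproduces
  the printed output and matches the SQL convention the symbols come from.
- `%` matches any, possibly empty, chain.
- Literal characters fold case and accents by default (`a_o_` finds
  `após`); a strict mode disables folding.
- Numeric operators are strict: `< x`, `> y`, and `< x > y` as the open
  interval `(y, x)`.
- Multiple criteria conjoin; `exclude` mode negates a criterion (an
  `enabled=False` switch disables one instead — the two readings of
  "whether a criterion should be considered" are both available).
- Statistics (max/min/mean of eight numeric columns) are computed over the
  full match set, as is CSV export; paging only windows the visible rows.

## Pseudoword generation

No published algorithm exists for the original engine, so the generator is
the simplest process whose outputs satisfy the attested-structure
constraint: left-to-right chain sampling. Bigram mode starts from a
position-1 `#x` bigram, extends at position p by bigrams attested at p that
overlap the last character, and terminates only on an `x#` bigram while the
length is within bounds (at the maximum length only terminal bigrams remain
eligible). Trigram mode is analogous with two-character overlap. Extensions
are weighted by positional type counts (a `uniform` switch flattens them).
Rejection sampling enforces novelty (no lexicon collision, no duplicate)
with `max_attempts = 1000 × count` by default; exhaustion returns the
partial list with a warning rather than failing or truncating silently.
Every run re-verifies that outputs are non-words with fully attested
positional n-grams.

## Cross-corpus comparison

External corpora are two-column TSVs (form, count), lower-cased on read
with accents preserved — folding accents across corpora would manufacture
overlap between genuinely different words. The lexicon side is
homograph-collapsed by summing. Alignment keeps types present with
positive frequency in every corpus. Correlations are Pearson on Zipf-scale
values, each corpus using its own token total (its frequency sum unless an
explicit total is supplied). Correlation differences use the
independent-samples Fisher r-to-z formula; a dependent-correlation variant
(the correlations share the reference corpus) is out of scope. Containment
is `|A ∩ B| / |A| × 100`, reported to 2 decimals; the identity
`cell(A,B)·|A| = cell(B,A)·|B|` is tested. The distribution profile applies
the standard outlier filters (letters > 20, neighbors > 40, OLD20 > 14,
homographs > 5, all configurable to ∞) and reports the removed fraction
plus type counts and mean-N/mean-OLD20 surfaces by length × category.

## Synthetic data

The generator emulates the one robust statistical property the pipeline
depends on — the Zipfian rank-frequency shape — with
`freq(r) = max(1, round(C·r^−a))`, C = 100,000 by default so a 1,000-type
lexicon has no clipping at either end. Forms are CV-alternating by default
so CVCV coding, neighborhoods and pseudoword chains are exercised on
pronounceable material; lengths are drawn from a normal with mean 9 and SD
3 (clipped to [1, 30]), matching typical written-corpus word lengths, and
the category mix defaults to nouns 40%, verbs 39%, adjectives 18% with the
closed categories sharing the remainder — the asymmetry characteristic of
POS-tagged written corpora. What the generator does **not** emulate:
morphology (no inflectional families), genre composition, accent
distribution, or realistic homography; tests passing on synthetic data
therefore validate algorithmic correctness and statistical invariants, not
linguistic coverage.

The fixed demo corpus embeds the canonical worked-example words (the
8-letter noun, a three-way homograph, the two wildcard example sets) plus
fillers — neighbor clusters, a hyphenated compound, accented and numeric
forms — so every column and both engines are non-degenerate at desk scale.
One word of the published wildcard fixture ("amora") is deliberately
replaced by "aposta": "amora" matches `am%`, contradicting the published
exact result set for that pattern, while "aposta" still discriminates
single-character `_` semantics from a one-or-more reading.

## Problem sizes and tolerances

Default test scales: neighborhood oracle equivalence on 200 random
lexicons (sizes up to 500 forms, 12 sampled probes each), n-gram window
identities on 10,000 random strings, search-engine brute-force equivalence
for 500 random criterion sets over a 5,000-type synthetic lexicon,
pseudoword guarantees over 100 seeded runs, Zipf-slope recovery at 1,000
types within ±0.1. The acceptance script uses 20 oracle lexicons of 20–120
forms and 2,000 strings; both scales give exact (1.0 / 0.0) agreement
rates since the checks are deterministic equalities. Stored numeric
columns round to 4 decimals (8 for the random column); OLD20 comparisons
in tests use 1e-4 absolute tolerance to match that storage precision.

## Known limitations

- Grammatical-information annotation is rule-table-driven; the shipped
  default table is illustrative, not a morphological analyzer.
- Lemma lists are carried through as counts only; no lemma-level columns
  are derived.
- Phonological/syllabic variables are out of scope.
- The pseudoword sampler is a documented stand-in for an unpublished
  engine: it honors the attested-structure constraints but its sampling
  distribution is its own.
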