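# lexikit

A psycholinguistic lexicon toolkit: from plain POS-tagged word-frequency
lists it builds a 25-column lexical database of the kind experimenters use
to select, control and match stimuli, then makes it searchable, comparable
across corpora, and usable for pseudoword generation.

## Who it is for

Researchers in psycholinguistics and computational linguistics who have
per-category frequency lists (one `form count` text file per grammatical
category — adjectives, adverbs, grammatical words, nouns, numerals, verbs,
proper names) and need the derived variables that word-recognition research
runs on:

- **Frequency transforms** — frequency per million tokens, log₁₀ frequency,
  the Zipf scale `zipf = log10(freq per million) + 3` (a corpus-size-free
  1–7 scale), and the dense Zipf rank (ties share a rank).
- **Orthographic structure** — letter counts, consonant/vowel (CVCV) coding
  with classes C/V/N/A/P/S, reversed forms, and bounded bigram/trigram
  decompositions (`cachorro → #c_ca_ac_ch_ho_or_rr_ro_o#`; a word of L
  letters has L+1 bigrams and L trigrams).
- **Corpus-relative measures** — orthographic uniqueness point, Coltheart's
  N (same-length neighbors at Hamming distance 1), OLD20 (mean Levenshtein
  distance to the 20 closest words), homograph counts and category listings.
- **Positional n-gram tables** — word-type counts per (category, position,
  n-gram), exportable as TSV, and per-word n-gram frequency sums.
- **Search engines** — a word-list engine and a multi-criterion engine with
  SQL-style wildcards (`_` exactly one character, `%` any chain) and strict
  range operators (`< x`, `> y`, `< x > y` open interval), accent- and
  case-insensitive by default, with paging, on-the-fly statistics and CSV
  export.
- **Pseudoword generation** — chain sampling over the positional n-gram
  tables so every output is a legal-looking nonword whose every positional
  n-gram is attested for the chosen category.
- **Cross-corpus comparison** — homograph collapsing, alignment on common
  types, Pearson correlation on the Zipf scale, Fisher r-to-z contrasts
  `z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))`, containment
  matrices and over/under-estimation lists.

A synthetic-data module generates Zipfian toy lexicons (and a fixed demo
corpus) so everything can be exercised without downloading any corpus.

## Worked example

```python
>>> import lexikit as lk
>>> lexicon = lk.demo_lexicon(seed=42)
>>> row = lexicon.frame[lexicon.frame["orthography"] == "cachorro"].iloc[0]
>>> row["nb_letters"], row["cvcv_ortho"], row["rev_ortho"]
(8, 'CVCCVCCV', 'orrohcac')
>>> row["bigrams"]
'#c_ca_ac_ch_ho_or_rr_ro_o#'
>>> from lexikit import frequency
>>> round(frequency.zipf_scale(397, 30_705_945), 4)   # 397 occurrences in a 30.7M-token corpus
4.1116
>>> round(frequency.per_million(397, 31_377_670), 4)
12.6523
```

The Zipf value 4.1116 says the word sits in the middle of the 1–7 scale —
a medium-frequency word (about 13 occurrences per million tokens). Querying
the same lexicon:

```python
>>> from lexikit import query
>>> hits = query.complex_search([query.Criterion("orthography", "a_o_")], lexicon)
>>> sorted(set(hits.matches["orthography"]))
['aloe', 'amor', 'anos', 'após']
```

`_` matched exactly one character, and the accent-folded default let
`após` through. The `examples/` directory holds one short script per
capability (building, searching, n-grams and pseudowords, corpus
comparison, synthetic data); each prints its results with a note on what
they mean.

A thin CLI mirrors the library:

```bash
lexikit simulate --types 1000 --seed 42 --out lists/
lexikit build --config build.yaml --seed 42 --out lexicon.csv
lexikit search --lexicon lexicon.csv --where "nb_letters < 5" --stats
lexikit pseudo --lexicon lexicon.csv --cat nom --n 25 --len 4:8 --seed 7
```

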