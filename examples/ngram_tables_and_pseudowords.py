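"""Positional n-gram tables and pseudoword generation.

The table counts word TYPES per (category, position, n-gram); pseudowords
are sampled left-to-right so that every positional n-gram of the output —
boundary n-grams included — is attested in the table, while the string
itself is absent from the lexicon.
"""

import lexikit as lk
from lexikit import orthography_ngrams as on, pseudoword as pw

lexicon = lk.demo_lexicon(seed=42)
table = on.build_ngram_table(lexicon, 2)

print(f"{len(table.counts)} positional bigram cells")
print("count(nom, position 1, '#c') =", table.count("nom", 1, "#c"),
      "(noun types starting with 'c')")

config = pw.PseudowordConfig(gram_cat="nom", count=8, length_min=3,
                             length_max=8, seed=7)
words = pw.generate_pseudowords(config, table, lexicon)
print("\npseudowords (noun bigram structure):")
for word in words:
    legality = pw.ngram_legality(word, "nom", table)
    print(f"  {word:<10} legality={legality}")
# legality sums the positional type counts of the string's bigrams: higher
# means more noun-like sub-lexical structure; real nouns score the same
# quantity as their bigram_freq column.

table.to_tsv("bigrams_nom.tsv")
print("\npositional table exported to bigrams_nom.tsv")
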