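"""Build the demonstration lexicon and inspect one entry's 25 columns.

The demo corpus is a small set of per-category frequency lists embedding
the canonical worked-example words. Building it runs the full pipeline:
cleaning, frequency transforms, orthographic coding, neighborhoods and
n-gram statistics.
"""

import lexikit as lk

lexicon = lk.demo_lexicon(seed=42)

print(f"{lexicon.type_total} word types, {lexicon.token_total} tokens")
print(f"types per category: {lexicon.category_types}\n")

row = lexicon.frame[lexicon.frame["orthography"] == "cachorro"].iloc[0]
for column in lk.COLUMNS:
    print(f"{column:>18}: {row[column]}")

# nb_letters counts every character; cvcv_ortho codes each one as
# consonant/vowel/etc.; the bigram and trigram strings are bounded by '#'
# and their counts obey letters+1 / letters; zipf_scale puts the raw
# frequency on a corpus-size-independent 1-7 scale.
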