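"""Query a lexicon with both search engines and export the result.

`_` substitutes exactly one character, `%` any chain; numeric criteria use
strict inequalities (`< x > y` is the open interval). Literal characters
match case- and accent-insensitively, so "a_o_" finds "após".
"""

import lexikit as lk
from lexikit import query

lexicon = lk.demo_lexicon(seed=42)

# simple engine: a word list, with unmatched words reported
result = query.simple_search(["cachorro", "ativa", "zzzz"], lexicon)
print(f"simple search: {result.total_found} entries, unmatched={result.unmatched}")

# complex engine: conjunction of wildcard and range criteria
criteria = [
    query.Criterion("orthography", "a%"),          # starts with 'a'
    query.Criterion("nb_letters", "< 6"),          # shorter than 6 letters
    query.Criterion("ortho_freq", "< 150 > 5"),    # frequency in (5, 150)
]
result = query.complex_search(criteria, lexicon, order=("orthography", "asc"))
print(f"\ncomplex search: {result.total_found} entries")
print(result.matches[["orthography", "gram_cat", "ortho_freq", "zipf_scale"]]
      .to_string(index=False))

stats = query.result_statistics(result)
print("\nper-column max/min/mean over the matches:")
print(stats.table.round(3).to_string())

query.export_csv(result, "search_result.csv")
print("\nfull result written to search_result.csv (all rows, quoted CSV)")
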