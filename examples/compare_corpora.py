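"""Cross-corpus frequency validation on the Zipf scale.

Homographs are collapsed (frequencies summed per orthographic form), the
corpora aligned on common positive-frequency types, correlated pairwise on
the Zipf scale, and coverage summarized as containment percentages and
over/under-estimated word lists.
"""

import numpy as np

import lexikit as lk

lexicon = lk.demo_lexicon(seed=42)
own = lk.collapse_homographs(lexicon, name="lexicon")

# a synthetic "other corpus": same words with noisy frequencies, plus a few
# words only it contains
rng = np.random.default_rng(0)
entries = {
    form: max(1, int(round(freq * rng.lognormal(0, 0.3))))
    for form, freq in own.entries.items()
}
entries.update({"zumbido": 40, "zelo": 12})
other = lk.CorpusFrequencyList("other", entries)

aligned = lk.align_corpora([own, other])
print(f"{len(aligned)} common word types")

r = lk.zipf_correlation(aligned, {"lexicon": own.token_total, "other": other.token_total})
print(f"Zipf-scale Pearson r = {r.loc['lexicon', 'other']:.4f}")

z = lk.fisher_rz_contrast(0.8, 45_968, 0.7, 45_968)
print(f"Fisher r-to-z contrast of r=.80 vs r=.70 at n=45,968: z = {z:.2f}")

containment = lk.containment_matrix([own, other])
print("\ncontainment (% of row types present in column corpus):")
print(containment.to_string())

over, under = lk.estimation_discrepancies(own, other, k=3)
print("\nwords only the lexicon attests (its most frequent misses):")
print(over.to_string(index=False))
print("\nwords only the other corpus attests:")
print(under.to_string(index=False))
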