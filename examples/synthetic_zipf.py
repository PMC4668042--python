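"""Generate a synthetic Zipfian lexicon and profile its distributions.

The generator draws distinct CV-alternating forms with frequencies
freq(rank r) = max(1, round(C * r^-a)); fitting log10 frequency against
log10 rank should recover the exponent a.
"""

import numpy as np

import lexikit as lk

spec = lk.SyntheticSpec(n_types=1000, zipf_exponent=1.0, seed=42)
lists = lk.generate_synthetic_lexicon(spec)
print({cat: len(entries) for cat, entries in lists.items()})

freqs = np.sort([e.raw_freq for lst in lists.values() for e in lst])[::-1].astype(float)
ranks = np.arange(1, freqs.size + 1)
slope = np.polyfit(np.log10(ranks), np.log10(freqs), 1)[0]
print(f"log-log rank-frequency slope: {slope:.3f} (target -1.0)")

lexicon, report = lk.build_lexicon(lists, seed=42)
print(f"built {lexicon.type_total} types; cleaning removed "
      f"{report.removed_numeric + report.removed_too_long} entries")

profile = lk.distribution_profile(lexicon)
print(f"outlier filters removed {profile.removed_fraction:.2%} of entries")
print("\nword types per grammatical category:")
print(profile.types_by_category.to_string())
print("\nmean OLD20 by length (first rows):")
print(profile.mean_old20_by_length_category.head(5).round(2).to_string())
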