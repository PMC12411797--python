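"""Generate a synthetic app-review study with known ground truth.

Draws a corpus of token documents from planted topics, folds planted
satisfaction/dissatisfaction effects into star ratings around each app's
comprehensive rating, and plants duplicates, bot flags and polarity
conflicts at known rates.
"""

import numpy as np

from kanosat.simulate import GeneratorConfig, generate_full_study

config = GeneratorConfig(n_docs=2000, vocab_size=400, doc_length_mean=30,
                         n_apps=20, seed=7)
dataset, truth = generate_full_study(config)

ratings = np.array([r.rating for r in dataset.reviews])
print(f"reviews generated          : {len(dataset)} (incl. planted duplicates)")
print(f"apps                       : {len(dataset.apps)}")
print(f"mean star rating           : {ratings.mean():.2f}")
print(f"planted bots / dups / confl: {len(truth.bot_ids)} / "
      f"{len(truth.duplicate_ids)} / {len(truth.conflict_ids)}")
print(f"planted effects (pd)       : {np.round(truth.beta_pd, 3)}")
# The flag sets are the ground truth the preprocessing stage is tested
# against; the beta vectors are what the Tobit stage should recover.
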