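"""Screen features by ANOVA and pick per-context medioids and outliers.

The screen keeps a feature column iff a one-way ANOVA across the three
contexts gives p < 0.05.  In the reduced (z-scored) space the medioid of
a context is the recording closest to the context centroid, the outlier
the one farthest from it.
"""

from meowdecode import (
    anova_screen,
    features_dataframe,
    select_exemplars,
    synth_corpus,
)

corpus = synth_corpus(n_per_class=8, seed=0)
feats = features_dataframe(corpus)
print(f"feature table: {feats.shape[0]} recordings x "
      f"{feats.shape[1] - 2} features")

screen = anova_screen(feats, alpha=0.05)
print("\nscreen decisions (kept iff p < 0.05):")
print(screen.table.to_string(index=False))
print(f"\nkept {len(screen.kept)}/10: {screen.kept}")

exemplars = select_exemplars(feats, screen.kept)
print("\nexemplars (distances in z-scored feature space):")
print(exemplars.to_frame().to_string(index=False))
# The medioid distance is always <= the outlier distance; these two clips
# per context are the ones a listener study would present.
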