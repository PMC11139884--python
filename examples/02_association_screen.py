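"""Screen features for association with the diagnosis label.

Plants a d = 1.0 group effect on the death-lexicon rate, then runs the
Mann–Whitney screen with Cohen's d and Monte-Carlo power over all 81
features and prints the strongest associations.
"""

from ptsdlang.corpus_io import tokenize
from ptsdlang.features import extract_all
from ptsdlang.stats import association_table
from ptsdlang.synthetic import (
    PlantedEffect,
    SyntheticConfig,
    binary_labels,
    generate_corpus,
    generate_lexicons,
)

cfg = SyntheticConfig(
    n_docs=148, exposure_split=(110, 38), diagnosis_split=(70, 42, 36),
    length_mean=600, length_sd=300, length_bounds=(150, 2000), seed=3,
    planted_effects=[PlantedEffect("model_death", d=1.0)])
corpus, metadata, _ = generate_corpus(cfg)
table = extract_all([tokenize(t) for t in corpus], generate_lexicons(3))

results = association_table(table, binary_labels(metadata),
                            group_order=[0, 1], power_reps=500, seed=3)
results.sort(key=lambda r: r.p_value)
print(f"{'feature':28s} {'p':>9s} {'d (cohen)':>10s} {'power':>6s}")
for r in results[:8]:
    print(f"{r.feature:28s} {r.p_value:9.2e} {r.effect_size:10.2f} "
          f"{r.power:6.2f}")
print("\nThe planted death-lexicon effect should top the list with a "
      "negative d (the symptomatic group uses more death words under the "
      "group1 − group2 sign convention) and power near 1.")
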