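"""Histone co-modification: per-class mean |level difference| per mark.

Planted pairs share a latent per-mark level plus noise on H3K27me3 and
X5mC only, so those two marks separate colocalized classes from the
background while the other 14 marks do not.
"""

from colocpair import (
    SyntheticConfig, bootstrap_summary, class_mod_similarity, classify_all,
    generate_dataset, mod_abs_diff, sample_no_colocalization,
)
from colocpair.classify import COLOCALIZED_CLASSES, class_pairs

dataset = generate_dataset(SyntheticConfig(seed=7))
table = classify_all(dataset.anchor, dataset.comparators.values(),
                     dataset.orthologs, dataset.interactions)
no_coloc = sorted(sample_no_colocalization(dataset.anchor, table, 500, 7))

for mark in ("H3K27me3", "X5mC", "H3K4me3"):
    print(f"\nmark {mark} (planted: {mark in dataset.config.planted_marks})")
    for label in COLOCALIZED_CLASSES:
        pairs = class_pairs(table, label)
        if not pairs:
            continue
        res = class_mod_similarity(pairs, dataset.modifications, mark,
                                   class_label=label)
        boot = bootstrap_summary(
            mod_abs_diff(pairs, dataset.modifications, mark), 200, seed=1)
        print(f"  {label:13s} mean|d|={res.observed:.3f} "
              f"+/- {boot.sd_of_means:.3f} (n={res.n_pairs_used})")
    base = class_mod_similarity(no_coloc, dataset.modifications, mark,
                                class_label="NO_COLOC")
    print(f"  {'NO_COLOC':13s} mean|d|={base.observed:.3f} (n={base.n_pairs_used})")
# Smaller mean |difference| = more similar modification levels. On the two
# planted marks every colocalized class beats the no-colocalization sample;
# on unplanted marks (e.g. H3K4me3) the classes look like background.
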