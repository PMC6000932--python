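"""Generate a synthetic genome-evolution dataset and write it as flat files.

The generator evolves comparator genomes from an anchor genome by clustered
gene loss, inversions and translocations, samples distance-decayed
intrachromosomal interaction pairs, and plants co-expression (rho) and
co-modification (shared latent level) effects on a disjoint set of
colocalized pairs.
"""

from colocpair import SyntheticConfig, generate_dataset, write_dataset

config = SyntheticConfig(seed=7)
dataset = generate_dataset(config)
paths = write_dataset(dataset, "example_out/synthetic")

print(f"anchor: {len(dataset.anchor)} genes on "
      f"{len(dataset.anchor.chromosomes)} chromosomes, "
      f"genome size {dataset.anchor.genome_size:,} bp")
for sp, ann in sorted(dataset.comparators.items()):
    truth = dataset.truth[sp].status
    n_n = sum(1 for s in truth.values() if s == "NEIGHBORING")
    n_s = sum(1 for s in truth.values() if s == "SEPARATED")
    n_a = sum(1 for s in truth.values() if s == "ABSENT")
    print(f"  {sp}: {len(ann)} genes | anchor-adjacent pairs there: "
          f"{n_n} neighboring, {n_s} separated, {n_a} absent")
print(f"interactions: {len(dataset.interactions)} same-chromosome pairs")
print(f"planted pairs: {len(dataset.planted_pairs)} "
      f"(rho={config.planted_corr}, noise ratio={config.planted_mod_similarity})")
print(f"wrote {len(paths)} files to example_out/synthetic/")
# The truth labels above are the generator's ground truth; the classifier
# must recover them exactly from the written annotation and ortholog files.
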