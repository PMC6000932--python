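"""Synthetic genome-evolution generator with planted, parameterized effects.

Generates an anchor genome, comparator genomes derived from it by clustered
gene loss, inversions and translocations (star phylogeny, per-branch rates),
an identity ortholog map (optionally many-to-many via tandem duplication),
distance-decayed intrachromosomal interaction pairs, and expression /
modification matrices in which a disjoint set of colocalized pairs carries a
planted correlation (expression) or a shared latent level (modification).

Ground truth: for every anchor-adjacent pair the comparator derivation also
emits its status (NEIGHBORING / SEPARATED / ABSENT) computed directly from
the simulated gene order, so classification can be checked against the
generator rather than against itself.

Gene loss is clustered: genes are dropped in contiguous segments (a two-state
Markov chain along the gene order whose marginal loss probability is the
configured rate and whose deleted runs have a configurable mean length).
Segmental deletion is how annotated genes actually disappear from synteny
comparisons, and it is what gives physically neighboring genes correlated
presence across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import ComparatorRates, SyntheticConfig, derive_seeds
from .errors import ConfigError, InputError
from .genome import (
    GenePair,
    GeneRecord,
    GenomeAnnotation,
    InteractionSet,
    OrthologTable,
    STATUS_ABSENT,
    STATUS_NEIGHBORING,
    STATUS_SEPARATED,
    gene_pair,
    neighboring_pairs,
)

Order = Dict[str, List[str]]  # chromosome -> gene ids in rank order


def _records_from_order(order: Order, strands: Dict[str, str],
                        gene_length: int, gene_gap: int) -> List[GeneRecord]:
    step = gene_length + gene_gap
    records = []
    for chrom in sorted(order):
        for i, gid in enumerate(order[chrom]):
            start = 1 + i * step
            records.append(GeneRecord(gid, chrom, start, start + gene_length - 1,
                                      strands.get(gid, "+")))
    return records


def _genome_size(n_genes: int, gene_length: int, gene_gap: int) -> int:
    return max(n_genes * (gene_length + gene_gap), 1)


def gen_anchor_genome(config: SyntheticConfig) -> GenomeAnnotation:
    """Anchor genome: n_genes in contiguous blocks over n_chromosomes.

    Coordinates are deterministic (1 kb genes, 1 kb gaps); strands are drawn
    from the anchor stream of the root seed. Same config => identical output.
    """
    seeds = derive_seeds(config.seed)
    rng = np.random.default_rng(seeds["anchor"])
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    width = len(str(config.n_genes))
    order: Order = {}
    gid = 0
    for c, count in enumerate(per_chrom):
        order[f"chr{c + 1}"] = [f"g{i + 1:0{width}d}" for i in range(gid, gid + count)]
        gid += count
    strands = {}
    for chrom in sorted(order):
        for g in order[chrom]:
            strands[g] = "+" if rng.random() < 0.5 else "-"
    records = _records_from_order(order, strands, config.gene_length, config.gene_gap)
    return GenomeAnnotation(
        "anchor", records,
        _genome_size(config.n_genes, config.gene_length, config.gene_gap),
    )


# ------------------------------------------------------------- rearrangements

def _clustered_loss(order: Order, loss_prob: float, run_mean: float,
                    rng: np.random.Generator) -> Set[str]:
    """Genes to drop: two-state Markov chain along each chromosome.

    Stationary loss probability equals ``loss_prob``; deleted runs have mean
    length ``run_mean`` (capped so the kept->lost rate stays a probability).
    """
    if loss_prob <= 0.0:
        return set()
    if loss_prob >= 1.0:
        return {g for genes in order.values() for g in genes}
    stay_lost = 1.0 - 1.0 / run_mean
    to_lost = min(loss_prob * (1.0 - stay_lost) / (1.0 - loss_prob), 1.0)
    lost: Set[str] = set()
    for chrom in sorted(order):
        state = rng.random() < loss_prob
        for g in order[chrom]:
            if state:
                lost.add(g)
            p = stay_lost if state else to_lost
            state = rng.random() < p
    return lost


def _apply_inversion(order: Order, strands: Dict[str, str],
                     rng: np.random.Generator) -> None:
    chroms = [c for c in sorted(order) if len(order[c]) >= 2]
    if not chroms:
        return
    weights = np.array([len(order[c]) for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
    genes = order[chrom]
    i, j = sorted(rng.choice(len(genes), size=2, replace=False))
    genes[i:j + 1] = genes[i:j + 1][::-1]
    for g in genes[i:j + 1]:
        strands[g] = "-" if strands.get(g, "+") == "+" else "+"


def _apply_translocation(order: Order, rng: np.random.Generator) -> None:
    sources = [c for c in sorted(order) if len(order[c]) >= 1]
    if len(order) < 2 or not sources:
        return
    weights = np.array([len(order[c]) for c in sources], dtype=float)
    src = sources[rng.choice(len(sources), p=weights / weights.sum())]
    genes = order[src]
    seg_len = min(1 + rng.geometric(0.5), len(genes))
    start = int(rng.integers(0, len(genes) - seg_len + 1))
    segment = genes[start:start + seg_len]
    del genes[start:start + seg_len]
    dests = [c for c in sorted(order) if c != src]
    dest = dests[int(rng.integers(0, len(dests)))]
    pos = int(rng.integers(0, len(order[dest]) + 1))
    order[dest][pos:pos] = segment


@dataclass
class ComparatorTruth:
    """Ground-truth per-anchor-adjacent-pair status in one comparator."""

    species_id: str
    status: Dict[GenePair, str] = field(default_factory=dict)


def derive_comparator(
    anchor: GenomeAnnotation,
    rates: ComparatorRates,
    seed: int,
    species_id: str,
    *,
    loss_run_mean: float = 8.0,
    tandem_dup_prob: float = 0.0,
    gene_length: int = 1000,
    gene_gap: int = 1000,
) -> Tuple[GenomeAnnotation, Dict[str, Dict[str, Set[str]]], ComparatorTruth]:
    """Evolve the anchor along one branch: losses -> inversions -> translocations.

    Returns the comparator annotation, ortholog entries
    (anchor gene -> {species_id: {comparator genes}}) and the ground-truth
    status of every anchor-adjacent pair in this comparator.
    """
    if len(anchor) == 0:
        raise InputError("anchor annotation is empty")
    if rates.inversions + rates.translocations > 0 and len(anchor) < 2:
        raise ConfigError("rearrangement rates exceed genome size")
    if rates.translocations > 0 and len(anchor.chromosomes) < 2:
        raise ConfigError("translocations require at least 2 chromosomes")
    rng = np.random.default_rng(seed)
    order: Order = {c: anchor.ordered_genes(c) for c in anchor.chromosomes}
    strands = {r.gene_id: r.strand for r in anchor.records}

    lost = _clustered_loss(order, rates.loss_prob, loss_run_mean, rng)
    order = {c: [g for g in genes if g not in lost] for c, genes in order.items()}

    # rename surviving genes into the comparator namespace; identity orthology
    entries: Dict[str, Dict[str, Set[str]]] = {}
    rename: Dict[str, str] = {}
    for c in sorted(order):
        for g in order[c]:
            comp_id = f"{species_id}|{g}"
            rename[g] = comp_id
            entries[g] = {species_id: {comp_id}}
    order = {c: [rename[g] for g in genes] for c, genes in order.items()}
    strands = {rename[g]: s for g, s in strands.items() if g in rename}

    if tandem_dup_prob > 0.0:
        for c in sorted(order):
            new_genes: List[str] = []
            for comp_id in order[c]:
                new_genes.append(comp_id)
                if rng.random() < tandem_dup_prob:
                    dup_id = comp_id + "~dup"
                    new_genes.append(dup_id)
                    strands[dup_id] = strands[comp_id]
                    anchor_gene = comp_id.split("|", 1)[1]
                    entries[anchor_gene][species_id].add(dup_id)
            order[c] = new_genes

    for _ in range(rates.inversions):
        _apply_inversion(order, strands, rng)
    for _ in range(rates.translocations):
        _apply_translocation(order, rng)

    n_comp = sum(len(v) for v in order.values())
    comparator = GenomeAnnotation(
        species_id,
        _records_from_order(order, strands, gene_length, gene_gap),
        _genome_size(n_comp, gene_length, gene_gap),
    )

    # ground truth from the simulated order itself (independent of classify)
    adjacent_comp: Set[GenePair] = set()
    for c, genes in order.items():
        for left, right in zip(genes, genes[1:]):
            adjacent_comp.add(gene_pair(left, right))
    truth = ComparatorTruth(species_id)
    for pair in neighboring_pairs(anchor):
        a, b = pair
        orth_a = entries.get(a, {}).get(species_id, set())
        orth_b = entries.get(b, {}).get(species_id, set())
        if not orth_a or not orth_b:
            truth.status[pair] = STATUS_ABSENT
        elif any(gene_pair(x, y) in adjacent_comp
                 for x in orth_a for y in orth_b if x != y):
            truth.status[pair] = STATUS_NEIGHBORING
        else:
            truth.status[pair] = STATUS_SEPARATED
    return comparator, entries, truth


# --------------------------------------------------------------- interactions

def gen_interactions(anchor: GenomeAnnotation, config: SyntheticConfig,
                     seed: int | None = None) -> InteractionSet:
    """Sample distinct same-chromosome pairs with P ~ (index distance)^-decay.

    decay = 0 is uniform sampling; larger decay concentrates contacts on
    physically close (including rank-adjacent) pairs, so the interaction set
    overlaps the adjacency universe the way Hi-C contact calls do.
    """
    if seed is None:
        seed = derive_seeds(config.seed)["interactions"]
    candidates: List[GenePair] = []
    weights: List[float] = []
    for chrom in anchor.chromosomes:
        genes = anchor.ordered_genes(chrom)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                candidates.append(gene_pair(genes[i], genes[j]))
                weights.append(float(j - i) ** (-config.interaction_decay))
    if not candidates:
        raise InputError("anchor has no chromosome with >= 2 genes")
    if config.n_interaction_pairs > len(candidates):
        raise ConfigError(
            f"requested {config.n_interaction_pairs} interaction pairs but only "
            f"{len(candidates)} same-chromosome pairs exist"
        )
    rng = np.random.default_rng(seed)
    w = np.asarray(weights)
    idx = rng.choice(len(candidates), size=config.n_interaction_pairs,
                     replace=False, p=w / w.sum())
    return InteractionSet({candidates[i] for i in idx})


# ------------------------------------------------------------------- planting

def select_planted_pairs(
    adjacent: Set[GenePair],
    interactions: InteractionSet,
) -> List[GenePair]:
    """Greedy maximal disjoint subset of the pair universe to plant effects on.

    Priority: interaction pairs that are also rank-adjacent first (these
    feed the rarest classes), then the remaining interaction pairs and the
    remaining adjacent pairs interleaved 1:2, so both the spatial-only and
    the linear-only classes keep a workable planted share of the limited
    gene budget. Deterministic: ties broken by canonical pair order.
    """
    first = sorted(interactions.pairs & adjacent)
    inter_only = sorted(interactions.pairs - adjacent)
    adj_only = sorted(adjacent - interactions.pairs)
    interleaved: List[GenePair] = []
    ia = ib = 0
    while ia < len(inter_only) or ib < len(adj_only):
        if ia < len(inter_only):
            interleaved.append(inter_only[ia])
            ia += 1
        interleaved.extend(adj_only[ib:ib + 2])
        ib += 2
    used: Set[str] = set()
    planted: List[GenePair] = []
    for a, b in first + interleaved:
        if a not in used and b not in used:
            planted.append((a, b))
            used.add(a)
            used.add(b)
    return planted


def _check_disjoint(planted_pairs: Sequence[GenePair]) -> None:
    seen: Set[str] = set()
    for a, b in planted_pairs:
        if a in seen or b in seen or a == b:
            raise InputError("planted pairs must be disjoint (no shared genes)")
        seen.add(a)
        seen.add(b)


def gen_expression(anchor: GenomeAnnotation, planted_pairs: Sequence[GenePair],
                   config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Gene x condition matrix; planted pairs are bivariate normal with rho."""
    _check_disjoint(planted_pairs)
    if seed is None:
        seed = derive_seeds(config.seed)["expression"]
    rng = np.random.default_rng(seed)
    genes = anchor.gene_ids
    values = rng.standard_normal((len(genes), config.n_conditions))
    frame = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"),
        columns=[f"cond{i + 1:02d}" for i in range(config.n_conditions)],
    )
    rho = config.planted_corr
    scale = np.sqrt(max(1.0 - rho * rho, 0.0))
    for a, b in planted_pairs:
        if a not in frame.index or b not in frame.index:
            raise InputError(f"planted pair ({a}, {b}) not in anchor")
        x = frame.loc[a].to_numpy()
        frame.loc[b] = rho * x + scale * rng.standard_normal(config.n_conditions)
    return frame


def gen_modifications(anchor: GenomeAnnotation, planted_pairs: Sequence[GenePair],
                      config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Gene x mark matrix; planted pairs share a latent level on planted marks.

    For a planted pair and a planted mark, both genes get
    latent + noise where noise s.d. = planted_mod_similarity (the latent
    level has unit s.d.), so the expected |difference| is
    2 * noise_sd / sqrt(pi). All other gene/mark levels are independent
    standard normal.
    """
    _check_disjoint(planted_pairs)
    if seed is None:
        seed = derive_seeds(config.seed)["modifications"]
    rng = np.random.default_rng(seed)
    genes = anchor.gene_ids
    frame = pd.DataFrame(
        rng.standard_normal((len(genes), len(config.marks))),
        index=pd.Index(genes, name="gene_id"), columns=list(config.marks),
    )
    sigma = config.planted_mod_similarity
    planted_mark_idx = [config.marks.index(m) for m in config.planted_marks]
    for a, b in planted_pairs:
        if a not in frame.index or b not in frame.index:
            raise InputError(f"planted pair ({a}, {b}) not in anchor")
        for mi in planted_mark_idx:
            latent = rng.standard_normal()
            frame.iloc[frame.index.get_loc(a), mi] = latent + sigma * rng.standard_normal()
            frame.iloc[frame.index.get_loc(b), mi] = latent + sigma * rng.standard_normal()
    return frame


# ---------------------------------------------------------------- the dataset

@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, generated from a single root seed."""

    config: SyntheticConfig
    anchor: GenomeAnnotation
    comparators: Dict[str, GenomeAnnotation]
    orthologs: OrthologTable
    truth: Dict[str, ComparatorTruth]
    interactions: InteractionSet
    planted_pairs: List[GenePair]
    expression: pd.DataFrame
    modifications: pd.DataFrame
    seeds: Dict[str, int]

    @property
    def species_rows(self) -> List[dict]:
        close = set(self.config.close_set)
        return [
            {"species_id": sp, "genome_size_bp": ann.genome_size,
             "close_set": int(sp in close)}
            for sp, ann in sorted(self.comparators.items())
        ]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator under the documented seed-splitting rule."""
    seeds = derive_seeds(config.seed)
    anchor = gen_anchor_genome(config)
    comp_seeds = np.random.SeedSequence(seeds["comparators"]).spawn(config.n_comparators)
    comparators: Dict[str, GenomeAnnotation] = {}
    truth: Dict[str, ComparatorTruth] = {}
    merged: Dict[str, Dict[str, Set[str]]] = {}
    for sp, rates, ss in zip(config.comparator_ids, config.comparator_rates, comp_seeds):
        child = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        comparator, entries, comp_truth = derive_comparator(
            anchor, rates, child, sp,
            loss_run_mean=config.loss_run_mean,
            tandem_dup_prob=config.tandem_dup_prob,
            gene_length=config.gene_length, gene_gap=config.gene_gap,
        )
        comparators[sp] = comparator
        truth[sp] = comp_truth
        for g, per_sp in entries.items():
            merged.setdefault(g, {}).update(per_sp)
    interactions = gen_interactions(anchor, config, seeds["interactions"])
    interactions.validate_same_chromosome(anchor)
    adjacent = neighboring_pairs(anchor)
    planted = select_planted_pairs(adjacent, interactions)
    expression = gen_expression(anchor, planted, config, seeds["expression"])
    modifications = gen_modifications(anchor, planted, config, seeds["modifications"])
    return SyntheticDataset(
        config=config, anchor=anchor, comparators=comparators,
        orthologs=OrthologTable(merged), truth=truth, interactions=interactions,
        planted_pairs=planted, expression=expression, modifications=modifications,
        seeds=seeds,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str) -> Dict[str, str]:
    """Write the dataset as flat files; returns the path map."""
    from . import io as _io

    _io.ensure_dir(out_dir)
    import os

    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    _io.write_gff3(dataset.anchor, p("anchor.gff3"))
    _io.write_annotation_tsv(dataset.anchor, p("anchor.tsv"))
    for sp, ann in sorted(dataset.comparators.items()):
        _io.write_annotation_tsv(ann, p(f"{sp}.tsv"))
    entries = {
        g: {sp: set(dataset.orthologs.orthologs(g, sp))
            for sp in dataset.orthologs.species
            if dataset.orthologs.orthologs(g, sp)}
        for g in dataset.orthologs.anchor_genes
    }
    clusters = {
        (g, sp, cg): f"clu_{g}"
        for g, per_sp in entries.items() for sp, cgs in per_sp.items() for cg in cgs
    }
    _io.write_ortholog_tsv(entries, clusters, p("orthologs.tsv"))
    _io.write_interaction_tsv(dataset.interactions, p("interactions.tsv"))
    _io.write_matrix_tsv(dataset.expression, p("expression.tsv"))
    _io.write_matrix_tsv(dataset.modifications, p("modifications.tsv"))
    _io.write_species_tsv(dataset.species_rows, p("species.tsv"))
    rows = []
    for sp in sorted(dataset.truth):
        for (a, b), status in sorted(dataset.truth[sp].status.items()):
            rows.append((a, b, sp, status))
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "species", "status"]) \
        .to_csv(p("truth.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(dataset.planted_pairs), columns=["gene_a", "gene_b"]) \
        .to_csv(p("planted_pairs.tsv"), sep="\t", index=False)
    return paths
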