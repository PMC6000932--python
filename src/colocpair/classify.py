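"""Colocalization flags and the seven exclusive pair classes.

A pair of anchor genes can carry three kinds of colocalization evidence:

* I — intrachromosomal colocalization: membership in the spatial
  interaction set;
* A — always-neighboring: the pair is rank-adjacent in the anchor and its
  orthologs are rank-adjacent in at least one comparator species;
* E — evolutionary neighboring: the pair is rank-adjacent in the anchor and
  its orthologs are both present but separated in at least one comparator.

The exclusive combination of (I, A, E) yields seven classes; interaction
pairs that are rank-adjacent but show neither A nor E evidence are labeled
NONE (the intrachromosomal-only class is defined on pairs that are *not*
linear neighbors) and their count is logged.

By default "at least one comparator" is the existential rule; the
alternative universal rule (every comparator where both orthologs are
present agrees) is available via ``rule="all"``.  Many-to-many orthologs
use the permissive any-combination rule: a pair is NEIGHBORING in a species
if any ortholog of one gene is adjacent to any ortholog of the other;
``combination_rule="all"`` requires every combination to be adjacent.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .errors import InputError
from .genome import (
    GenePair,
    GenomeAnnotation,
    InteractionSet,
    OrthologTable,
    STATUS_ABSENT,
    STATUS_NEIGHBORING,
    STATUS_SEPARATED,
    adjacency_index,
    gene_pair,
    neighboring_pairs,
)

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "INTRA_ONLY", "ALWAYS_ONLY", "EVO_ONLY", "INTRA_ALWAYS",
    "INTRA_EVO", "ALWAYS_EVO", "ALL_THREE", "NONE",
)
COLOCALIZED_CLASSES = CLASS_LABELS[:-1]


def pair_status(
    pair: GenePair,
    comparator: GenomeAnnotation,
    orthologs: OrthologTable,
    *,
    adjacency: Optional[Mapping[str, Set[str]]] = None,
    combination_rule: str = "any",
) -> str:
    """Status of one anchor pair in one comparator species.

    ABSENT if either gene has no ortholog there; NEIGHBORING if ortholog
    copies are rank-adjacent (any-combination rule by default); otherwise
    SEPARATED.
    """
    a, b = pair
    orth_a = orthologs.orthologs(a, comparator.species_id)
    orth_b = orthologs.orthologs(b, comparator.species_id)
    if not orth_a or not orth_b:
        return STATUS_ABSENT
    for g in orth_a | orth_b:
        if g not in comparator:
            raise InputError(
                f"ortholog {g!r} of pair ({a}, {b}) missing from "
                f"{comparator.species_id} annotation"
            )
    if adjacency is None:
        adjacency = adjacency_index(comparator)
    combos = [
        (x, y) for x in orth_a for y in orth_b if x != y
    ]
    if not combos:
        return STATUS_ABSENT
    hits = [y in adjacency.get(x, ()) for x, y in combos]
    if combination_rule == "any":
        return STATUS_NEIGHBORING if any(hits) else STATUS_SEPARATED
    if combination_rule == "all":
        return STATUS_NEIGHBORING if all(hits) else STATUS_SEPARATED
    raise InputError(f"unknown combination_rule {combination_rule!r}")


def assign_flags(
    pair: GenePair,
    anchor_adjacent: bool,
    statuses: Mapping[str, str],
    interactions: InteractionSet,
    *,
    rule: str = "any",
) -> Dict[str, object]:
    """Flags (I, A, E) and the exclusive class label for one pair."""
    intra = pair in interactions
    values = list(statuses.values())
    if rule == "any":
        has_n = STATUS_NEIGHBORING in values
        has_s = STATUS_SEPARATED in values
    elif rule == "all":
        present = [v for v in values if v != STATUS_ABSENT]
        has_n = bool(present) and all(v == STATUS_NEIGHBORING for v in present)
        has_s = bool(present) and all(v == STATUS_SEPARATED for v in present)
    else:
        raise InputError(f"unknown rule {rule!r}")
    flag_a = anchor_adjacent and has_n
    flag_e = anchor_adjacent and has_s
    label = _class_label(intra, flag_a, flag_e, anchor_adjacent)
    return {
        "gene_a": pair[0], "gene_b": pair[1],
        "anchor_adjacent": anchor_adjacent,
        "I": intra, "A": flag_a, "E": flag_e, "class_label": label,
    }


def _class_label(intra: bool, flag_a: bool, flag_e: bool, adjacent: bool) -> str:
    if flag_a and flag_e:
        return "ALL_THREE" if intra else "ALWAYS_EVO"
    if flag_a:
        return "INTRA_ALWAYS" if intra else "ALWAYS_ONLY"
    if flag_e:
        return "INTRA_EVO" if intra else "EVO_ONLY"
    if intra and not adjacent:
        return "INTRA_ONLY"
    # interaction pairs that are linear neighbors without A/E evidence do
    # not qualify as intrachromosomal-only ("without being linear neighbors")
    return "NONE"


def classify_all(
    anchor: GenomeAnnotation,
    comparators: Iterable[GenomeAnnotation],
    orthologs: OrthologTable,
    interactions: InteractionSet,
    *,
    rule: str = "any",
    combination_rule: str = "any",
) -> pd.DataFrame:
    """Classify the full pair universe (anchor-adjacent U interaction pairs).

    Returns one row per pair: gene_a, gene_b, anchor_adjacent, I, A, E,
    class_label and one ``status_<species>`` column per comparator.
    """
    comparators = list(comparators)
    adjacent = neighboring_pairs(anchor) if len(anchor) > 1 else set()
    universe = sorted(set(adjacent) | set(interactions.pairs))
    if not universe:
        raise InputError("empty pair universe: no adjacent or interaction pairs")
    adjacency_cache = {c.species_id: adjacency_index(c) for c in comparators}
    rows: List[dict] = []
    for pair in universe:
        statuses = {
            c.species_id: pair_status(
                pair, c, orthologs,
                adjacency=adjacency_cache[c.species_id],
                combination_rule=combination_rule,
            )
            for c in comparators
        }
        row = assign_flags(pair, pair in adjacent, statuses, interactions, rule=rule)
        for sp, st in statuses.items():
            row[f"status_{sp}"] = st
        rows.append(row)
    frame = pd.DataFrame(rows)
    n_adjacent_intra_none = int(
        ((frame["class_label"] == "NONE") & frame["I"] & frame["anchor_adjacent"]).sum()
    )
    if n_adjacent_intra_none:
        logger.info(
            "%d interaction pairs are linear neighbors without A/E evidence; "
            "labeled NONE (excluded from INTRA_ONLY)", n_adjacent_intra_none,
        )
    return frame


def status_columns(classified: pd.DataFrame) -> List[str]:
    return [c for c in classified.columns if c.startswith("status_")]


def class_pairs(classified: pd.DataFrame, label: str) -> List[GenePair]:
    sub = classified[classified["class_label"] == label]
    return [gene_pair(a, b) for a, b in zip(sub["gene_a"], sub["gene_b"])]


def sample_no_colocalization(
    anchor: GenomeAnnotation,
    classified: pd.DataFrame,
    n: int,
    seed: int,
) -> Set[GenePair]:
    """n distinct gene pairs with no colocalization evidence, sampled uniformly.

    Eligible pairs are unordered pairs of anchor genes that are not
    rank-adjacent, not in the interaction universe, and (being non-adjacent)
    carry no A/E flag. Uniformity over the eligible set is achieved by
    uniform index sampling over all C(n_genes, 2) pairs with rejection of
    the excluded ones.
    """
    if n == 0:
        return set()
    genes = sorted(anchor.gene_ids)
    n_genes = len(genes)
    total = n_genes * (n_genes - 1) // 2
    excluded = {
        gene_pair(a, b) for a, b in zip(classified["gene_a"], classified["gene_b"])
    }
    if total - len(excluded) < n:
        raise InputError(
            f"need {n} no-colocalization pairs but only "
            f"{total - len(excluded)} are eligible"
        )
    rng = np.random.default_rng(seed)
    chosen: Set[GenePair] = set()
    while len(chosen) < n:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        pair = gene_pair(genes[int(i)], genes[int(j)])
        if pair in excluded or pair in chosen:
            continue
        chosen.add(pair)
    return chosen
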