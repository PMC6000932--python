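"""Independent brute-force reference for pair classification.

Deliberately naive: re-sorts gene orders from scratch, enumerates every
ortholog combination with nested loops, and never shares code with the
package's classification path, so it can serve as an oracle on small
genomes.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple


def _sorted_orders(annotation) -> Dict[str, List[str]]:
    chrom_map: Dict[str, list] = {}
    for rec in annotation.records:
        chrom_map.setdefault(rec.chromosome, []).append(rec)
    return {
        chrom: [r.gene_id for r in sorted(recs, key=lambda r: (r.start, r.end, r.gene_id))]
        for chrom, recs in chrom_map.items()
    }


def _adjacent_pairs(orders: Dict[str, List[str]]) -> Set[Tuple[str, str]]:
    out = set()
    for genes in orders.values():
        for i in range(len(genes) - 1):
            a, b = genes[i], genes[i + 1]
            out.add((min(a, b), max(a, b)))
    return out


def brute_force_classify(anchor, comparators, orthologs, interactions,
                         rule: str = "any") -> Dict[Tuple[str, str], dict]:
    """Classification of the pair universe by exhaustive enumeration."""
    anchor_adjacent = _adjacent_pairs(_sorted_orders(anchor))
    interaction_pairs = {(min(a, b), max(a, b)) for a, b in interactions.pairs}
    universe = sorted(anchor_adjacent | interaction_pairs)
    comp_adjacent = {
        comp.species_id: _adjacent_pairs(_sorted_orders(comp)) for comp in comparators
    }
    result: Dict[Tuple[str, str], dict] = {}
    for a, b in universe:
        statuses = {}
        for comp in comparators:
            sp = comp.species_id
            orth_a = orthologs.orthologs(a, sp)
            orth_b = orthologs.orthologs(b, sp)
            combos = [(x, y) for x in orth_a for y in orth_b if x != y]
            if not combos:
                statuses[sp] = "ABSENT"
                continue
            neighboring = False
            for x, y in combos:
                if (min(x, y), max(x, y)) in comp_adjacent[sp]:
                    neighboring = True
                    break
            statuses[sp] = "NEIGHBORING" if neighboring else "SEPARATED"
        adjacent = (a, b) in anchor_adjacent
        intra = (a, b) in interaction_pairs
        vals = list(statuses.values())
        if rule == "any":
            has_n = "NEIGHBORING" in vals
            has_s = "SEPARATED" in vals
        else:
            present = [v for v in vals if v != "ABSENT"]
            has_n = bool(present) and all(v == "NEIGHBORING" for v in present)
            has_s = bool(present) and all(v == "SEPARATED" for v in present)
        flag_a = adjacent and has_n
        flag_e = adjacent and has_s
        if flag_a and flag_e:
            label = "ALL_THREE" if intra else "ALWAYS_EVO"
        elif flag_a:
            label = "INTRA_ALWAYS" if intra else "ALWAYS_ONLY"
        elif flag_e:
            label = "INTRA_EVO" if intra else "EVO_ONLY"
        elif intra and not adjacent:
            label = "INTRA_ONLY"
        else:
            label = "NONE"
        result[(a, b)] = {
            "anchor_adjacent": adjacent, "I": intra, "A": flag_a, "E": flag_e,
            "class_label": label, "statuses": statuses,
        }
    return result


def random_small_config(rng) -> "object":
    """A random small SyntheticConfig for oracle-equivalence sweeps."""
    from colocpair import ComparatorRates, SyntheticConfig

    n_chrom = int(rng.integers(1, 4))
    n_genes = int(rng.integers(max(8, 2 * n_chrom), 51))
    n_comp = int(rng.integers(1, 6))
    rates = []
    for _ in range(n_comp):
        loss = float(rng.choice([0.0, 0.1, 0.3, 0.5, 1.0],
                                p=[0.2, 0.25, 0.25, 0.25, 0.05]))
        rates.append(ComparatorRates(
            inversions=int(rng.integers(0, 5)),
            translocations=int(rng.integers(0, 3)) if n_chrom >= 2 else 0,
            loss_prob=loss,
        ))
    max_pairs = 0
    per = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        per[i] += 1
    for m in per:
        max_pairs += m * (m - 1) // 2
    return SyntheticConfig(
        n_genes=n_genes, n_chromosomes=n_chrom, n_comparators=n_comp,
        comparator_rates=rates, n_close=min(1, n_comp),
        n_interaction_pairs=int(rng.integers(1, min(10, max_pairs) + 1)),
        interaction_decay=float(rng.uniform(0, 2)),
        n_conditions=5, n_marks=2, marks=("H3K27me3", "X5mC"),
        tandem_dup_prob=float(rng.choice([0.0, 0.2], p=[0.6, 0.4])),
        loss_run_mean=float(rng.uniform(1.5, 6)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
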