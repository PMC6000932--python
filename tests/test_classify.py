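"""Pair statuses, colocalization flags, the seven-class partition, and the
no-colocalization sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from colocpair import (
    GeneRecord,
    GenomeAnnotation,
    InputError,
    InteractionSet,
    OrthologTable,
    classify_all,
    gene_pair,
    pair_status,
    sample_no_colocalization,
)
from colocpair.classify import assign_flags, class_pairs
from conftest import small_config
from _reference import brute_force_classify


def _ann(species, genes_by_chrom):
    records = []
    for chrom, genes in genes_by_chrom.items():
        for i, g in enumerate(genes):
            start = 1 + 100 * i
            records.append(GeneRecord(g, chrom, start, start + 50))
    return GenomeAnnotation(species, records, 10_000)


class TestPairStatus:
    def setup_method(self):
        self.comp = _ann("sp1", {"c1": ["h1", "h2", "h3"]})

    def test_adjacent_orthologs_are_neighboring(self):
        orth = OrthologTable({"g1": {"sp1": ["h1"]}, "g2": {"sp1": ["h2"]}})
        assert pair_status(("g1", "g2"), self.comp, orth) == "NEIGHBORING"

    def test_missing_ortholog_is_absent(self):
        orth = OrthologTable({"g2": {"sp1": ["h2"]}})
        assert pair_status(("g1", "g2"), self.comp, orth) == "ABSENT"

    def test_non_adjacent_orthologs_are_separated(self):
        orth = OrthologTable({"g1": {"sp1": ["h1"]}, "g2": {"sp1": ["h3"]}})
        assert pair_status(("g1", "g2"), self.comp, orth) == "SEPARATED"

    def test_any_ortholog_combination_suffices(self):
        """g1 -> {h1, h1b}; only the co-ortholog h1b neighbors h2."""
        comp = _ann("sp1", {"c1": ["h1", "x", "h1b", "h2"]})
        orth = OrthologTable({"g1": {"sp1": ["h1", "h1b"]}, "g2": {"sp1": ["h2"]}})
        assert pair_status(("g1", "g2"), comp, orth) == "NEIGHBORING"
        # strict rule: (h1, h2) is not adjacent, so not every combination holds
        assert pair_status(("g1", "g2"), comp, orth, combination_rule="all") \
            == "SEPARATED"

    def test_unknown_comparator_gene_rejected(self):
        orth = OrthologTable({"g1": {"sp1": ["nope"]}, "g2": {"sp1": ["h2"]}})
        with pytest.raises(InputError):
            pair_status(("g1", "g2"), self.comp, orth)

    def test_symmetric_in_gene_order(self):
        orth = OrthologTable({"g1": {"sp1": ["h1"]}, "g2": {"sp1": ["h2"]}})
        assert pair_status(("g1", "g2"), self.comp, orth) == \
            pair_status(("g2", "g1"), self.comp, orth)


class TestAssignFlags:
    def test_interaction_without_adjacency_is_intra_only(self):
        inter = InteractionSet.from_pairs([("g1", "g3")])
        row = assign_flags(("g1", "g3"), False,
                           {"sp1": "ABSENT", "sp2": "ABSENT"}, inter)
        assert row["class_label"] == "INTRA_ONLY"
        assert row["I"] and not row["A"] and not row["E"]

    def test_always_and_evo_without_interaction(self):
        inter = InteractionSet.from_pairs([])
        row = assign_flags(("g1", "g2"), True,
                           {"sp1": "NEIGHBORING", "sp2": "SEPARATED"}, inter)
        assert row["class_label"] == "ALWAYS_EVO"

    def test_no_evidence_is_none(self):
        inter = InteractionSet.from_pairs([])
        row = assign_flags(("g1", "g2"), True,
                           {"sp1": "ABSENT", "sp2": "ABSENT"}, inter)
        assert row["class_label"] == "NONE"

    def test_adjacent_interaction_without_ae_is_none_not_intra_only(self):
        inter = InteractionSet.from_pairs([("g1", "g2")])
        row = assign_flags(("g1", "g2"), True,
                           {"sp1": "ABSENT"}, inter)
        assert row["class_label"] == "NONE"
        assert row["I"]

    def test_universal_rule_requires_agreement(self):
        inter = InteractionSet.from_pairs([])
        statuses = {"sp1": "NEIGHBORING", "sp2": "SEPARATED"}
        row = assign_flags(("g1", "g2"), True, statuses, inter, rule="all")
        assert not row["A"] and not row["E"]
        statuses = {"sp1": "NEIGHBORING", "sp2": "ABSENT"}
        row = assign_flags(("g1", "g2"), True, statuses, inter, rule="all")
        assert row["A"]


class TestClassifyAll:
    def test_partition_covers_universe(self, default_classified):
        counts = default_classified["class_label"].value_counts()
        assert counts.sum() == len(default_classified)
        # classes are pairwise disjoint by construction: one row per pair
        pairs = set(zip(default_classified["gene_a"], default_classified["gene_b"]))
        assert len(pairs) == len(default_classified)

    def test_identity_comparators_never_set_evo_flag(self):
        cfg = small_config(seed=4)
        from colocpair import ComparatorRates, generate_dataset

        cfg = small_config(seed=4, comparator_rates=[
            ComparatorRates(0, 0, 0.0)] * 3)
        ds = generate_dataset(cfg)
        table = classify_all(ds.anchor, ds.comparators.values(), ds.orthologs,
                             ds.interactions)
        assert not table["E"].any()
        adjacent = table[table["anchor_adjacent"]]
        assert adjacent["A"].all()

    def test_interaction_pair_with_unknown_orthologs_is_all_absent(self):
        anchor = _ann("anchor", {"c1": ["g1", "g2", "g3"]})
        comp = _ann("sp1", {"c1": ["h1", "h2"]})
        orth = OrthologTable({"g1": {"sp1": ["h1"]}, "g2": {"sp1": ["h2"]}})
        inter = InteractionSet.from_pairs([("g1", "g3")])
        table = classify_all(anchor, [comp], orth, inter)
        row = table[(table["gene_a"] == "g1") & (table["gene_b"] == "g3")].iloc[0]
        assert row["status_sp1"] == "ABSENT"
        assert row["class_label"] == "INTRA_ONLY"

    def test_empty_universe_rejected(self):
        anchor = _ann("anchor", {"c1": ["g1"], "c2": ["g2"]})
        with pytest.raises(InputError):
            classify_all(anchor, [], OrthologTable({}),
                         InteractionSet.from_pairs([]))

    def test_matches_brute_force_on_small_genomes(self, rng):
        """Spot equivalence on a handful of small random configurations
        (the full 100-genome sweep runs in the acceptance suite)."""
        from colocpair import generate_dataset
        from _reference import random_small_config

        for _ in range(10):
            cfg = random_small_config(rng)
            ds = generate_dataset(cfg)
            mine = classify_all(ds.anchor, ds.comparators.values(),
                                ds.orthologs, ds.interactions)
            ref = brute_force_classify(ds.anchor, ds.comparators.values(),
                                       ds.orthologs, ds.interactions)
            assert len(mine) == len(ref)
            for row in mine.itertuples(index=False):
                expected = ref[(row.gene_a, row.gene_b)]
                assert row.class_label == expected["class_label"]
                for sp, status in expected["statuses"].items():
                    assert getattr(row, f"status_{sp}") == status


class TestNoColocalizationSample:
    def test_zero_draws(self, default_dataset, default_classified):
        assert sample_no_colocalization(default_dataset.anchor,
                                        default_classified, 0, 1) == set()

    def test_reproducible_and_disjoint_from_universe(self, default_dataset,
                                                     default_classified):
        s1 = sample_no_colocalization(default_dataset.anchor,
                                      default_classified, 100, 42)
        s2 = sample_no_colocalization(default_dataset.anchor,
                                      default_classified, 100, 42)
        assert s1 == s2
        universe = set(zip(default_classified["gene_a"],
                           default_classified["gene_b"]))
        assert not (s1 & universe)

    def test_uniform_over_eligible_pairs(self):
        """Goodness of fit on repeated draws from a 10-gene genome."""
        anchor = _ann("anchor", {"c1": [f"g{i}" for i in range(10)]})
        comp = _ann("sp1", {"c1": ["h0"]})
        orth = OrthologTable({"g0": {"sp1": ["h0"]}})
        inter = InteractionSet.from_pairs([("g0", "g5")])
        table = classify_all(anchor, [comp], orth, inter)
        excluded = set(zip(table["gene_a"], table["gene_b"]))
        eligible = sorted(
            gene_pair(f"g{i}", f"g{j}")
            for i in range(10) for j in range(i + 1, 10)
            if gene_pair(f"g{i}", f"g{j}") not in excluded
        )
        counts = dict.fromkeys(eligible, 0)
        n_runs, per_run = 1000, 3
        for seed in range(n_runs):
            for p in sample_no_colocalization(anchor, table, per_run, seed):
                counts[p] += 1
        observed = np.array(list(counts.values()))
        expected = np.full(len(eligible), n_runs * per_run / len(eligible))
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=len(eligible) - 1) > 0.01

    def test_insufficient_pairs_rejected(self):
        anchor = _ann("anchor", {"c1": ["g1", "g2", "g3"]})
        comp = _ann("sp1", {"c1": ["h1"]})
        table = classify_all(anchor, [comp], OrthologTable({}),
                             InteractionSet.from_pairs([("g1", "g3")]))
        with pytest.raises(InputError):
            sample_no_colocalization(anchor, table, 5, 0)
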