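"""The synthetic genome-evolution generator: determinism, rearrangement
semantics, interaction sampling, and the planted-effect distributions."""

import numpy as np
import pytest
from scipy import stats as sps

from colocpair import (
    ComparatorRates,
    ConfigError,
    InputError,
    SyntheticConfig,
    derive_comparator,
    gen_anchor_genome,
    gen_expression,
    gen_interactions,
    gen_modifications,
    generate_dataset,
    neighboring_pairs,
    select_planted_pairs,
    write_dataset,
)
from conftest import small_config


def tiny_config(**overrides):
    defaults = dict(
        n_genes=10, n_chromosomes=1, n_comparators=1,
        comparator_rates=[ComparatorRates(0, 0, 0.0)], n_close=0,
        n_interaction_pairs=3, n_conditions=10, n_marks=2,
        marks=("H3K27me3", "X5mC"), seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


class TestAnchorGenome:
    def test_layout_and_bookkeeping(self):
        cfg = tiny_config(n_genes=6, n_chromosomes=2)
        ann = gen_anchor_genome(cfg)
        assert len(ann) == 6
        assert [len(ann.ordered_genes(c)) for c in ann.chromosomes] == [3, 3]
        for chrom in ann.chromosomes:
            recs = [ann.gene(g) for g in ann.ordered_genes(chrom)]
            for left, right in zip(recs, recs[1:]):
                assert left.end < right.start  # non-overlapping, increasing
        assert ann.genome_size == 6 * 2000

    def test_single_gene_genome(self):
        ann = gen_anchor_genome(tiny_config(n_genes=1, n_chromosomes=1))
        assert len(ann) == 1
        assert neighboring_pairs(ann) == set()

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_genes=0)
        with pytest.raises(ConfigError):
            SyntheticConfig(planted_corr=1.5)
        with pytest.raises(ConfigError):
            SyntheticConfig(n_marks=1)


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        cfg_a, cfg_b = small_config(seed=5), small_config(seed=5)
        ds_a, ds_b = generate_dataset(cfg_a), generate_dataset(cfg_b)
        assert ds_a.expression.equals(ds_b.expression)
        assert ds_a.modifications.equals(ds_b.modifications)
        assert ds_a.interactions.pairs == ds_b.interactions.pairs
        assert ds_a.planted_pairs == ds_b.planted_pairs
        for sp in ds_a.truth:
            assert ds_a.truth[sp].status == ds_b.truth[sp].status

    def test_written_files_byte_identical(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            ds = generate_dataset(small_config(seed=9))
            out = tmp_path / name
            write_dataset(ds, str(out))
            outs.append(out)
        for f in sorted(outs[0].iterdir()):
            assert f.read_bytes() == (outs[1] / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        a = generate_dataset(small_config(seed=1))
        b = generate_dataset(small_config(seed=2))
        assert not a.expression.equals(b.expression)


class TestDeriveComparator:
    def test_identity_evolution_keeps_every_pair_neighboring(self):
        anchor = gen_anchor_genome(tiny_config())
        _, _, truth = derive_comparator(anchor, ComparatorRates(0, 0, 0.0), 3, "c")
        assert set(truth.status.values()) == {"NEIGHBORING"}

    def test_total_loss_makes_every_pair_absent(self):
        anchor = gen_anchor_genome(tiny_config())
        comp, entries, truth = derive_comparator(anchor, ComparatorRates(0, 0, 1.0), 3, "c")
        assert len(comp) == 0
        assert entries == {}
        assert set(truth.status.values()) == {"ABSENT"}

    @pytest.mark.parametrize("seed", range(12))
    def test_single_inversion_breaks_at_most_two_adjacencies(self, seed):
        """Brute-force recomputation of before/after adjacency on a 10-gene toy."""
        anchor = gen_anchor_genome(tiny_config())
        comp, entries, truth = derive_comparator(
            anchor, ComparatorRates(1, 0, 0.0), seed, "c")
        # reference: recompute adjacency of the comparator order directly
        order = comp.ordered_genes("chr1")
        adj_after = {
            tuple(sorted(p)) for p in zip(order, order[1:])
        }
        for (a, b), status in truth.status.items():
            ca = next(iter(entries[a]["c"]))
            cb = next(iter(entries[b]["c"]))
            expected = "NEIGHBORING" if tuple(sorted((ca, cb))) in adj_after \
                else "SEPARATED"
            assert status == expected
        n_separated = sum(1 for s in truth.status.values() if s == "SEPARATED")
        assert n_separated <= 2  # only the segment-boundary pairs can change

    def test_translocation_requires_second_chromosome(self):
        anchor = gen_anchor_genome(tiny_config())
        with pytest.raises(ConfigError):
            derive_comparator(anchor, ComparatorRates(0, 1, 0.0), 0, "c")

    def test_tandem_duplication_creates_many_to_many(self):
        anchor = gen_anchor_genome(tiny_config(n_genes=30))
        _, entries, _ = derive_comparator(
            anchor, ComparatorRates(0, 0, 0.0), 11, "c", tandem_dup_prob=0.4)
        n_multi = sum(1 for per_sp in entries.values() if len(per_sp["c"]) > 1)
        assert n_multi > 0

    def test_marginal_loss_rate_matches_setting(self):
        """Clustered loss still drops each gene at the stated marginal rate."""
        cfg = tiny_config(n_genes=400)
        anchor = gen_anchor_genome(cfg)
        kept = []
        for seed in range(40):
            comp, _, _ = derive_comparator(
                anchor, ComparatorRates(0, 0, 0.3), seed, "c", loss_run_mean=8.0)
            kept.append(len(comp))
        mean_loss = 1 - np.mean(kept) / 400
        assert abs(mean_loss - 0.3) < 0.05

    def test_clustered_loss_correlates_neighbor_fate(self):
        """Adjacent genes are lost together more often than independently."""
        cfg = tiny_config(n_genes=400)
        anchor = gen_anchor_genome(cfg)
        order = anchor.ordered_genes("chr1")
        both_lost = one_lost = 0
        for seed in range(30):
            comp, _, _ = derive_comparator(
                anchor, ComparatorRates(0, 0, 0.5), seed, "c", loss_run_mean=8.0)
            surviving = {r.gene_id.split("|", 1)[1] for r in comp.records}
            for a, b in zip(order, order[1:]):
                la, lb = a not in surviving, b not in surviving
                if la and lb:
                    both_lost += 1
                elif la != lb:
                    one_lost += 1
        # independent loss at 0.5 would give both_lost ~= one_lost / 2
        assert both_lost > one_lost


class TestInteractions:
    def test_unique_pair_two_gene_genome(self):
        cfg = tiny_config(n_genes=2, n_interaction_pairs=1)
        inter = gen_interactions(gen_anchor_genome(cfg), cfg)
        assert len(inter) == 1

    def test_pairs_share_chromosome(self):
        cfg = small_config(seed=3)
        anchor = gen_anchor_genome(cfg)
        inter = gen_interactions(anchor, cfg)
        inter.validate_same_chromosome(anchor)

    def test_too_many_pairs_requested(self):
        cfg = tiny_config(n_genes=3, n_interaction_pairs=4)
        with pytest.raises(ConfigError):
            gen_interactions(gen_anchor_genome(cfg), cfg)

    def test_zero_decay_is_uniform(self):
        """Chi-square goodness of fit over all same-chromosome pairs."""
        cfg = tiny_config(n_genes=8, interaction_decay=0.0, n_interaction_pairs=5)
        anchor = gen_anchor_genome(cfg)
        counts = {}
        n_draws = 2000
        for seed in range(n_draws):
            for pair in gen_interactions(anchor, cfg, seed=seed).pairs:
                counts[pair] = counts.get(pair, 0) + 1
        n_pairs = 8 * 7 // 2
        observed = np.array([counts.get(p, 0) for p in sorted(counts)])
        assert len(counts) == n_pairs
        expected = np.full(n_pairs, 5 * n_draws / n_pairs)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, df=n_pairs - 1)
        assert p > 0.01

    def test_decay_favors_short_range(self):
        cfg = tiny_config(n_genes=60, interaction_decay=2.0,
                          n_interaction_pairs=30)
        anchor = gen_anchor_genome(cfg)
        order = {g: i for i, g in enumerate(anchor.ordered_genes("chr1"))}
        dists = []
        for seed in range(50):
            for a, b in gen_interactions(anchor, cfg, seed=seed).pairs:
                dists.append(abs(order[a] - order[b]))
        assert np.median(dists) <= 3


class TestExpression:
    def test_perfect_correlation_when_rho_one(self):
        cfg = tiny_config(planted_corr=1.0, n_conditions=25)
        anchor = gen_anchor_genome(cfg)
        expr = gen_expression(anchor, [("g01", "g02")], cfg, seed=5)
        r = np.corrcoef(expr.loc["g01"], expr.loc["g02"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_indistinguishable_from_background(self):
        """Mean sample r over many planted pairs stays within 3 s.e. of 0."""
        cfg = SyntheticConfig(
            n_genes=2000, n_chromosomes=1, n_comparators=1,
            comparator_rates=[ComparatorRates(0, 0, 0.0)], n_close=0,
            n_interaction_pairs=1, planted_corr=0.0, n_conditions=30,
            n_marks=2, marks=("H3K27me3", "X5mC"), seed=0,
        )
        anchor = gen_anchor_genome(cfg)
        genes = anchor.gene_ids
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(1000)]
        expr = gen_expression(anchor, pairs, cfg, seed=8)
        vals = expr.to_numpy()
        loc = {g: i for i, g in enumerate(expr.index)}
        rs = [np.corrcoef(vals[loc[a]], vals[loc[b]])[0, 1] for a, b in pairs]
        se = 1 / np.sqrt(cfg.n_conditions - 1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se

    def test_planted_fraction_matches_sampling_distribution(self):
        """Fraction of planted pairs with r >= 0.5 vs an independent
        Monte-Carlo of the sampling distribution of r-hat at rho=0.6, n=50."""
        rho, n_cond, n_pairs = 0.6, 50, 500
        cfg = SyntheticConfig(
            n_genes=2 * n_pairs, n_chromosomes=1, n_comparators=1,
            comparator_rates=[ComparatorRates(0, 0, 0.0)], n_close=0,
            n_interaction_pairs=1, planted_corr=rho, n_conditions=n_cond,
            n_marks=2, marks=("H3K27me3", "X5mC"), seed=0,
        )
        anchor = gen_anchor_genome(cfg)
        genes = anchor.gene_ids
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs)]
        expr = gen_expression(anchor, pairs, cfg, seed=13)
        vals = expr.to_numpy()
        loc = {g: i for i, g in enumerate(expr.index)}
        rs = np.array([np.corrcoef(vals[loc[a]], vals[loc[b]])[0, 1]
                       for a, b in pairs])
        observed = (rs >= 0.5).mean()
        # independent oracle: simulate r-hat directly from bivariate normals
        oracle_rng = np.random.default_rng(99)
        m = 4000
        x = oracle_rng.standard_normal((m, n_cond))
        y = rho * x + np.sqrt(1 - rho**2) * oracle_rng.standard_normal((m, n_cond))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r_hat = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        p_expected = (r_hat >= 0.5).mean()
        tol = 3 * np.sqrt(p_expected * (1 - p_expected) / n_pairs) + 0.01
        assert abs(observed - p_expected) < tol

    def test_overlapping_planted_pairs_rejected(self):
        cfg = tiny_config()
        anchor = gen_anchor_genome(cfg)
        with pytest.raises(InputError):
            gen_expression(anchor, [("g01", "g02"), ("g02", "g03")], cfg, seed=1)


class TestModifications:
    def test_zero_noise_means_identical_levels(self):
        cfg = tiny_config(planted_mod_similarity=1e-12)
        anchor = gen_anchor_genome(cfg)
        mods = gen_modifications(anchor, [("g01", "g02")], cfg, seed=2)
        for mark in cfg.planted_marks:
            assert abs(mods.loc["g01", mark] - mods.loc["g02", mark]) < 1e-9

    def test_mean_abs_diff_matches_closed_form(self):
        """E|X - Y| = 2*sigma/sqrt(pi) for the planted noise model."""
        sigma = 0.3
        cfg = SyntheticConfig(
            n_genes=2000, n_chromosomes=1, n_comparators=1,
            comparator_rates=[ComparatorRates(0, 0, 0.0)], n_close=0,
            n_interaction_pairs=1, planted_mod_similarity=sigma,
            n_conditions=5, n_marks=2, marks=("H3K27me3", "X5mC"), seed=0,
        )
        anchor = gen_anchor_genome(cfg)
        genes = anchor.gene_ids
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(1000)]
        mods = gen_modifications(anchor, pairs, cfg, seed=3)
        col = mods["H3K27me3"]
        diffs = np.array([abs(col[a] - col[b]) for a, b in pairs])
        expected = 2 * sigma / np.sqrt(np.pi)
        assert diffs.mean() == pytest.approx(expected, rel=0.1)

    def test_planted_pairs_more_similar_than_background(self):
        cfg = tiny_config(n_genes=400, planted_mod_similarity=0.3)
        anchor = gen_anchor_genome(cfg)
        genes = anchor.gene_ids
        planted = [(genes[2 * i], genes[2 * i + 1]) for i in range(80)]
        background = [(genes[2 * i], genes[2 * i + 1]) for i in range(80, 190)]
        mods = gen_modifications(anchor, planted, cfg, seed=4)
        col = mods["X5mC"]
        d_planted = np.mean([abs(col[a] - col[b]) for a, b in planted])
        d_back = np.mean([abs(col[a] - col[b]) for a, b in background])
        assert d_planted < d_back

    def test_required_marks_present(self):
        cfg = small_config()
        mods = gen_modifications(gen_anchor_genome(cfg), [], cfg, seed=0)
        assert {"H3K27me3", "X5mC"} <= set(mods.columns)
        assert len(mods.columns) == cfg.n_marks


class TestPlanting:
    def test_planted_pairs_disjoint_and_prioritized(self, default_dataset):
        seen = set()
        for a, b in default_dataset.planted_pairs:
            assert a not in seen and b not in seen
            seen.update((a, b))
        adjacent = neighboring_pairs(default_dataset.anchor)
        overlap = default_dataset.interactions.pairs & adjacent
        planted = set(default_dataset.planted_pairs)
        # the rare interaction-and-adjacent pairs are planted almost entirely
        assert len(overlap & planted) / len(overlap) > 0.7


class TestClassCoverage:
    def test_default_config_populates_all_seven_classes(self, default_classified):
        labels = set(default_classified["class_label"])
        for label in ("INTRA_ONLY", "ALWAYS_ONLY", "EVO_ONLY", "INTRA_ALWAYS",
                      "INTRA_EVO", "ALWAYS_EVO", "ALL_THREE"):
            assert label in labels, label
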