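"""End-to-end orchestration: simulate -> classify -> co-expression ->
co-modification -> conservation -> phylogenetic coefficients -> report.

A run is driven by one :class:`~colocpair.config.RunConfig` and one root
seed; every stage takes its own derived seed (recorded in the report), all
stage outputs are flat TSVs and the whole run is summarized in a single
machine-readable ``report.json`` whose provenance block suffices to rerun
any stage.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import io as _io
from .classify import (
    COLOCALIZED_CLASSES,
    class_pairs,
    classify_all,
    sample_no_colocalization,
    status_columns,
)
from .config import RunConfig, config_to_dict, derive_seeds
from .conservation import (
    class_conservation,
    conservation_counts,
    phylo_coefficients_per_species,
    species_distribution,
)
from .errors import ColocError, InputError, StageError
from .genome import GenePair, STATUS_ABSENT, gene_pair
from .similarity import class_mod_similarity, coexpr_fraction
from .stats import (
    NEW_BASE,
    OLD_BASE,
    bootstrap_summary,
    mann_whitney_u,
    permutation_null,
    relative_change,
)
from .synthetic import generate_dataset, write_dataset
from .worked import worked_examples

logger = logging.getLogger(__name__)

# Fig 2-4-style combination comparisons: (combined class, reference class)
COMBINATION_COMPARISONS = (
    ("INTRA_ALWAYS", "ALWAYS_ONLY"),
    ("INTRA_EVO", "EVO_ONLY"),
    ("ALWAYS_EVO", "ALWAYS_ONLY"),
    ("ALL_THREE", "INTRA_ALWAYS"),
    ("ALL_THREE", "INTRA_EVO"),
    ("ALL_THREE", "ALWAYS_EVO"),
)

NO_COLOC = "NO_COLOC"


def _standardized_rows(matrix: pd.DataFrame):
    """Row-standardized matrix for fast rowwise Pearson correlations."""
    values = matrix.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[norm == 0] = np.nan
    z = centered / norm[:, None]
    loc = {g: i for i, g in enumerate(matrix.index)}
    return z, loc


def _pair_index(pairs: Sequence[GenePair], loc: Dict[str, int]):
    ia = np.array([loc[a] for a, _ in pairs], dtype=int)
    ib = np.array([loc[b] for _, b in pairs], dtype=int)
    return ia, ib


def _coexpr_statistic(z: np.ndarray, loc: Dict[str, int],
                      threshold: float) -> Callable[[List[GenePair]], float]:
    def stat(pairs: List[GenePair]) -> float:
        ia, ib = _pair_index(pairs, loc)
        r = (z[ia] * z[ib]).sum(axis=1)
        r = r[~np.isnan(r)]
        return float((r >= threshold).mean()) if r.size else float("nan")

    return stat


def _mod_statistic(levels: np.ndarray, loc: Dict[str, int]
                   ) -> Callable[[List[GenePair]], float]:
    def stat(pairs: List[GenePair]) -> float:
        ia, ib = _pair_index(pairs, loc)
        return float(np.abs(levels[ia] - levels[ib]).mean())

    return stat


def _conservation_statistic(presence: np.ndarray, loc: Dict[str, int]
                            ) -> Callable[[List[GenePair]], float]:
    def stat(pairs: List[GenePair]) -> float:
        ia, ib = _pair_index(pairs, loc)
        return float((presence[ia] & presence[ib]).sum(axis=1).mean())

    return stat


def run_all(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute every stage and return (and write) the analysis report."""
    out_dir = out_dir or config.out_dir
    _io.ensure_dir(out_dir)
    seeds = derive_seeds(config.seed)
    report: dict = {
        "provenance": {
            "package_version": _pkg_version,
            "root_seed": config.seed,
            "stage_seeds": seeds,
            "config": config_to_dict(config),
        },
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)

        def fail(exc: Exception):
            raise StageError(name, str(exc)) from exc

        return fail

    # ---------------------------------------------------------------- simulate
    fail = stage("simulate")
    try:
        syn = config.synthetic
        syn.seed = config.seed
        dataset = generate_dataset(syn)
        write_dataset(dataset, os.path.join(out_dir, "synthetic"))
    except ColocError as exc:
        fail(exc)
    planted = set(dataset.planted_pairs)
    report["stages"]["simulate"] = {
        "n_genes": len(dataset.anchor),
        "n_comparators": len(dataset.comparators),
        "n_interactions": len(dataset.interactions),
        "n_planted_pairs": len(planted),
    }

    # ---------------------------------------------------------------- classify
    fail = stage("classify")
    try:
        classified = classify_all(
            dataset.anchor, dataset.comparators.values(),
            dataset.orthologs, dataset.interactions,
        )
    except ColocError as exc:
        fail(exc)
    classified.to_csv(os.path.join(out_dir, "pairs.tsv"), sep="\t", index=False)
    class_counts = classified["class_label"].value_counts().to_dict()
    report["stages"]["classify"] = {
        "n_pairs": int(len(classified)),
        "class_counts": {k: int(v) for k, v in class_counts.items()},
    }

    no_coloc = sorted(sample_no_colocalization(
        dataset.anchor, classified, config.n_no_coloc, seeds["no_coloc"],
    ))
    pd.DataFrame(no_coloc, columns=["gene_a", "gene_b"]).to_csv(
        os.path.join(out_dir, "no_coloc.tsv"), sep="\t", index=False)

    pairs_by_class: Dict[str, List[GenePair]] = {
        label: class_pairs(classified, label) for label in COLOCALIZED_CLASSES
    }
    pairs_by_class[NO_COLOC] = list(no_coloc)
    genes = dataset.anchor.gene_ids

    perm_children = np.random.SeedSequence(seeds["permutation"]).spawn(4096)
    perm_iter = iter(perm_children)
    boot_children = np.random.SeedSequence(seeds["bootstrap"]).spawn(4096)
    boot_iter = iter(boot_children)

    def next_seed(it) -> int:
        return int(next(it).generate_state(1, dtype=np.uint32)[0] % (2**31))

    # ------------------------------------------------------------------ coexpr
    fail = stage("coexpr")
    z, zloc = _standardized_rows(dataset.expression)
    coexpr_rows = []
    coexpr_results: Dict[str, Dict[float, dict]] = {}
    try:
        for label, pairs in pairs_by_class.items():
            if not pairs:
                logger.info("coexpr: class %s empty, skipped", label)
                continue
            coexpr_results[label] = {}
            for threshold in config.thresholds:
                res = coexpr_fraction(pairs, dataset.expression, threshold,
                                      class_label=label)
                indicator = _coexpr_statistic(z, zloc, threshold)
                res.bootstrap = _fraction_bootstrap(
                    pairs, z, zloc, threshold, config.n_boot, next_seed(boot_iter))
                res.permutation = permutation_null(
                    indicator, len(pairs), genes, config.n_perm,
                    next_seed(perm_iter), direction="greater",
                    observed=res.observed,
                )
                coexpr_results[label][threshold] = res.to_dict()
                coexpr_rows.append({
                    "class_label": label, "threshold": threshold,
                    "fraction": res.observed, "n_pairs_used": res.n_pairs_used,
                    "empirical_p": res.permutation.empirical_p,
                })
    except ColocError as exc:
        fail(exc)
    pd.DataFrame(coexpr_rows).to_csv(os.path.join(out_dir, "coexpr.tsv"),
                                     sep="\t", index=False)
    report["stages"]["coexpr"] = coexpr_results

    # ------------------------------------------------------------------- comod
    fail = stage("comod")
    mod_values = dataset.modifications
    comod_rows = []
    comod_results: Dict[str, Dict[str, dict]] = {}
    try:
        for label, pairs in pairs_by_class.items():
            if not pairs:
                continue
            comod_results[label] = {}
            for mark in config.marks_of_interest:
                res = class_mod_similarity(pairs, mod_values, mark,
                                           class_label=label)
                levels = mod_values[mark].to_numpy(dtype=float)
                mloc = {g: i for i, g in enumerate(mod_values.index)}
                stat = _mod_statistic(levels, mloc)
                diffs = np.abs(levels[[mloc[a] for a, _ in pairs]]
                               - levels[[mloc[b] for _, b in pairs]])
                res.bootstrap = bootstrap_summary(diffs, config.n_boot,
                                                  next_seed(boot_iter))
                res.permutation = permutation_null(
                    stat, len(pairs), genes, config.n_perm,
                    next_seed(perm_iter), direction="less",
                    observed=res.observed,
                )
                comod_results[label][mark] = res.to_dict()
                comod_rows.append({
                    "class_label": label, "mark": mark,
                    "mean_abs_diff": res.observed,
                    "n_pairs_used": res.n_pairs_used,
                    "empirical_p": res.permutation.empirical_p,
                })
    except ColocError as exc:
        fail(exc)
    pd.DataFrame(comod_rows).to_csv(os.path.join(out_dir, "comod.tsv"),
                                    sep="\t", index=False)
    report["stages"]["comod"] = comod_results

    # ---------------------------------------------------------- conservation
    fail = stage("conserve")
    try:
        species = [c[len("status_"):] for c in status_columns(classified)]
        presence = np.zeros((len(genes), len(species)), dtype=bool)
        gloc = {g: i for i, g in enumerate(genes)}
        for j, sp in enumerate(species):
            for g in genes:
                if dataset.orthologs.orthologs(g, sp):
                    presence[gloc[g], j] = True
        cons_stat = _conservation_statistic(presence, gloc)
        cons_results = {}
        cons_counts: Dict[str, np.ndarray] = {}
        for label in COLOCALIZED_CLASSES:
            pairs = pairs_by_class[label]
            if not pairs:
                continue
            profile = class_conservation(
                classified, label, n_boot=config.n_boot,
                seed=next_seed(boot_iter))
            perm = permutation_null(
                cons_stat, len(pairs), genes, config.n_perm,
                next_seed(perm_iter), direction="greater",
                observed=profile.mean,
            )
            cons_counts[label] = profile.counts
            entry = profile.to_dict()
            entry["permutation"] = perm.to_dict()
            cons_results[label] = entry
        # no-colocalization sample: counts from ortholog presence
        ia, ib = _pair_index(list(no_coloc), gloc)
        nc_counts = (presence[ia] & presence[ib]).sum(axis=1).astype(float)
        cons_counts[NO_COLOC] = nc_counts
        cons_results[NO_COLOC] = {
            "class_label": NO_COLOC, "mean": float(nc_counts.mean()),
            "n_pairs": int(nc_counts.size),
            "bootstrap": bootstrap_summary(
                nc_counts, config.n_boot, next_seed(boot_iter)).to_dict(),
        }
        dist = species_distribution(
            classified, dataset.config.close_set,
            classes=list(COLOCALIZED_CLASSES),
        )
        spearman = dist.close_share_spearman()
    except ColocError as exc:
        fail(exc)
    pd.DataFrame([
        {"class_label": lbl, "mean_count": entry["mean"],
         "n_pairs": entry["n_pairs"]}
        for lbl, entry in cons_results.items()
    ]).to_csv(os.path.join(out_dir, "conservation.tsv"), sep="\t", index=False)
    dist.per_class_species.to_csv(
        os.path.join(out_dir, "species_distribution.tsv"), sep="\t")
    report["stages"]["conserve"] = {
        "classes": cons_results,
        "close_set": dist.close_set,
        "close_share_by_level": {
            int(k): (None if np.isnan(v) else float(v))
            for k, v in dist.close_share_by_level.items()
        },
        "close_share_spearman": None if np.isnan(spearman) else float(spearman),
    }

    # ------------------------------------------------------------------- phylo
    fail = stage("phylo")
    try:
        sizes = {sp: ann.genome_size for sp, ann in dataset.comparators.items()}
        coeffs = phylo_coefficients_per_species(
            classified, len(dataset.anchor), sizes, dataset.anchor.genome_size)
    except ColocError as exc:
        fail(exc)
    pd.DataFrame([c.to_dict() for c in coeffs]).to_csv(
        os.path.join(out_dir, "phylo.tsv"), sep="\t", index=False)
    report["stages"]["phylo"] = [c.to_dict() for c in coeffs]

    # ------------------------------------------------------------------ report
    fail = stage("report")
    try:
        comparisons = []
        for comb, ref in COMBINATION_COMPARISONS:
            if comb not in pairs_by_class or ref not in pairs_by_class:
                continue
            if not pairs_by_class[comb] or not pairs_by_class[ref]:
                continue
            for threshold in config.thresholds:
                fa = coexpr_results[comb][threshold]["observed"] * 100
                fb = coexpr_results[ref][threshold]["observed"] * 100
                if fa != 0:
                    comparisons.append({
                        "quantity": f"coexpr_fraction_t{threshold}",
                        "combined": comb, "reference": ref,
                        "a": fa, "b": fb, "convention": NEW_BASE,
                        "relative_change_pct": relative_change(fa, fb, NEW_BASE),
                    })
            for mark in config.marks_of_interest:
                da = comod_results[ref][mark]["observed"]
                db = comod_results[comb][mark]["observed"]
                if da != 0:
                    comparisons.append({
                        "quantity": f"mod_abs_diff_{mark}_similarity_gain",
                        "combined": comb, "reference": ref,
                        "a": da, "b": db, "convention": NEW_BASE,
                        "relative_change_pct": relative_change(da, db, NEW_BASE),
                    })
            if comb in cons_counts and ref in cons_counts:
                ca, cb = cons_counts[comb], cons_counts[ref]
                test = mann_whitney_u(ca, cb)
                comparisons.append({
                    "quantity": "mean_conservation_count",
                    "combined": comb, "reference": ref,
                    "a": float(ca.mean()), "b": float(cb.mean()),
                    "convention": OLD_BASE,
                    "relative_change_pct": relative_change(
                        float(ca.mean()), float(cb.mean()), OLD_BASE)
                    if cb.mean() != 0 else None,
                    "mann_whitney": test.to_dict(),
                })
        report["comparisons"] = comparisons
        report["worked_examples"] = worked_examples()
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except ColocError as exc:
        fail(exc)
    return report


def _fraction_bootstrap(pairs, z, loc, threshold, n_boot, seed):
    """Bootstrap the co-expressed fraction over the class's pairs."""
    ia, ib = _pair_index(pairs, loc)
    r = (z[ia] * z[ib]).sum(axis=1)
    indicator = (r[~np.isnan(r)] >= threshold).astype(float)
    if indicator.size == 0:
        raise InputError("no defined correlations to bootstrap")
    return bootstrap_summary(indicator, n_boot=n_boot, seed=seed)
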