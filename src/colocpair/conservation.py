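"""Cross-species conservation of pair classes and the phylogenetic coefficient.

A pair is "found" in a comparator when both genes have orthologs there
(status != ABSENT); the stricter found-as-neighbors rule is available via
``found_rule="neighboring"``. The conservation count of a pair is the number
of comparators where it is found; per class we report the mean count with a
bootstrap error. The species-distribution summary gives, per class and
species, the fraction of class pairs found there, and — per conservation
level k — the share of found-pair incidences that fall in a designated
phylogenetically close species set (the curve whose downward trend links
conservation level to phylogenetic distance).

The phylogenetic coefficient for one comparator is r = r1 * r2 with
r1 = 2*N_n/N_A (fraction of anchor genes involved in always-neighboring
pairs against that comparator) and r2 = T_c/T_A (genome-size ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import status_columns
from .errors import InputError
from .genome import STATUS_ABSENT, STATUS_NEIGHBORING
from .stats import BootstrapSummary, bootstrap_summary


def _found_matrix(classified: pd.DataFrame, found_rule: str = "present") -> pd.DataFrame:
    """Boolean pair x species matrix of the found relation."""
    cols = status_columns(classified)
    if not cols:
        raise InputError("classification table has no status_<species> columns")
    sub = classified[cols]
    if found_rule == "present":
        found = sub != STATUS_ABSENT
    elif found_rule == "neighboring":
        found = sub == STATUS_NEIGHBORING
    else:
        raise InputError(f"unknown found_rule {found_rule!r}")
    found.columns = [c[len("status_"):] for c in cols]
    return found


def species_count(statuses: Mapping[str, str], found_rule: str = "present") -> int:
    """Number of comparator species where one pair is found."""
    if found_rule == "present":
        return sum(1 for s in statuses.values() if s != STATUS_ABSENT)
    if found_rule == "neighboring":
        return sum(1 for s in statuses.values() if s == STATUS_NEIGHBORING)
    raise InputError(f"unknown found_rule {found_rule!r}")


@dataclass
class ConservationProfile:
    """Per-pair conservation counts and the per-class mean with error bar."""

    class_label: str
    counts: np.ndarray
    mean: float
    bootstrap: Optional[BootstrapSummary] = None

    def to_dict(self) -> dict:
        d = {"class_label": self.class_label, "mean": self.mean,
             "n_pairs": int(self.counts.size)}
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict()
        return d


def conservation_counts(classified: pd.DataFrame,
                        found_rule: str = "present") -> pd.Series:
    """Conservation count per pair (row-aligned with the classification table)."""
    return _found_matrix(classified, found_rule).sum(axis=1)


def class_conservation(
    classified: pd.DataFrame,
    class_label: str,
    *,
    found_rule: str = "present",
    n_boot: int = 1000,
    seed: int = 0,
) -> ConservationProfile:
    """Mean conservation count of one class, with bootstrap error bar."""
    mask = classified["class_label"] == class_label
    if not mask.any():
        raise InputError(f"class {class_label!r} is empty")
    counts = conservation_counts(classified[mask], found_rule).to_numpy(dtype=float)
    return ConservationProfile(
        class_label=class_label, counts=counts, mean=float(counts.mean()),
        bootstrap=bootstrap_summary(counts, n_boot=n_boot, seed=seed),
    )


@dataclass
class SpeciesDistribution:
    """Found-fractions per class x species and the close-set share per level."""

    per_class_species: pd.DataFrame        # index class, columns species
    close_share_by_level: pd.Series        # index conservation level k
    close_set: List[str]

    def close_share_spearman(self) -> float:
        """Spearman rank correlation of close-set share against level k."""
        from scipy.stats import spearmanr

        share = self.close_share_by_level.dropna()
        if share.size < 2:
            return float("nan")
        rho, _ = spearmanr(share.index.to_numpy(), share.to_numpy())
        return float(rho)


def species_distribution(
    classified: pd.DataFrame,
    close_set: Sequence[str],
    *,
    classes: Optional[Sequence[str]] = None,
    found_rule: str = "present",
) -> SpeciesDistribution:
    """Per class x species found-fractions and the close-set share per level.

    The close-set share at conservation level k pools every pair (of the
    selected classes) found in exactly k species and reports which fraction
    of those found-incidences lie in the close species set.
    """
    found = _found_matrix(classified, found_rule)
    species = list(found.columns)
    unknown = set(close_set) - set(species)
    if unknown:
        raise InputError(f"close_set species not among comparators: {sorted(unknown)}")
    labels = classified["class_label"]
    if classes is None:
        classes = sorted(labels.unique())
    rows = {}
    for label in classes:
        mask = (labels == label).to_numpy()
        if mask.sum() == 0:
            continue
        rows[label] = found[mask].mean(axis=0)
    per_class = pd.DataFrame(rows).T
    per_class.index.name = "class_label"

    keep = labels.isin(classes).to_numpy()
    sub = found[keep]
    level = sub.sum(axis=1)
    close_cols = [s for s in species if s in set(close_set)]
    share = {}
    max_level = len(species)
    for k in range(1, max_level + 1):
        at_k = sub[level == k]
        total = int(at_k.to_numpy().sum())
        if total == 0:
            share[k] = float("nan")
        else:
            share[k] = float(at_k[close_cols].to_numpy().sum() / total)
    return SpeciesDistribution(
        per_class_species=per_class,
        close_share_by_level=pd.Series(share, name="close_share"),
        close_set=list(close_set),
    )


@dataclass
class PhyloCoefficient:
    """r = r1 * r2 for one comparator species."""

    species_id: str
    n_always_pairs: int      # N_n
    n_anchor_genes: int      # N_A
    genome_size_comparator: float  # T_c
    genome_size_anchor: float      # T_A
    r1: float
    r2: float
    r: float

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id, "N_n": self.n_always_pairs,
            "N_A": self.n_anchor_genes, "T_c": self.genome_size_comparator,
            "T_A": self.genome_size_anchor, "r1": self.r1, "r2": self.r2,
            "r": self.r,
        }


def phylo_coefficient(n_always_pairs: int, n_anchor_genes: int,
                      genome_size_comparator: float, genome_size_anchor: float,
                      species_id: str = "") -> PhyloCoefficient:
    """Direct phylogenetic factor times genome amplification factor."""
    if n_anchor_genes <= 0:
        raise InputError("n_anchor_genes (N_A) must be > 0")
    if genome_size_anchor <= 0:
        raise InputError("genome_size_anchor (T_A) must be > 0")
    if n_always_pairs < 0 or genome_size_comparator < 0:
        raise InputError("N_n and T_c must be >= 0")
    r1 = 2.0 * n_always_pairs / n_anchor_genes
    r2 = genome_size_comparator / genome_size_anchor
    return PhyloCoefficient(
        species_id=species_id, n_always_pairs=n_always_pairs,
        n_anchor_genes=n_anchor_genes,
        genome_size_comparator=genome_size_comparator,
        genome_size_anchor=genome_size_anchor,
        r1=r1, r2=r2, r=r1 * r2,
    )


def phylo_coefficients_per_species(
    classified: pd.DataFrame,
    n_anchor_genes: int,
    genome_sizes: Mapping[str, float],
    genome_size_anchor: float,
) -> List[PhyloCoefficient]:
    """N_n per species = anchor-adjacent pairs whose status there is NEIGHBORING."""
    out = []
    adjacent = classified[classified["anchor_adjacent"]]
    for col in status_columns(classified):
        sp = col[len("status_"):]
        if sp not in genome_sizes:
            raise InputError(f"no genome size for species {sp!r}")
        n_n = int((adjacent[col] == STATUS_NEIGHBORING).sum())
        out.append(phylo_coefficient(
            n_n, n_anchor_genes, float(genome_sizes[sp]),
            float(genome_size_anchor), species_id=sp,
        ))
    return out
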