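"""Resampling machinery: permutation nulls, bootstrap errors, Mann-Whitney U,
and the two relative-change conventions.

The permutation null draws the same number of uniformly random distinct gene
pairs as the observed class and re-evaluates the statistic; the empirical p
uses the add-one estimator (1 + exceed) / (1 + n), which can never be zero.
The Mann-Whitney test uses midranks for ties, exact enumeration of the
conditional rank distribution for small samples, and a tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from .errors import InputError, UndefinedStatistic
from .genome import GenePair

EXACT_LIMIT = 12  # n1 + n2 at or below this -> exact enumeration


@dataclass
class BootstrapSummary:
    """Mean and the s.d. of resampled means (the reported error bar)."""

    mean: float
    sd_of_means: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd_of_means": self.sd_of_means,
                "n_boot": self.n_boot, "seed": self.seed}


@dataclass
class PermutationResult:
    """Observed statistic against a null of random gene pairs."""

    observed: float
    n_perm: int
    null_mean: float
    null_sd: float
    exceed_count: int
    empirical_p: float
    seed: int
    direction: str
    n_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed, "n_perm": self.n_perm,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "exceed_count": self.exceed_count, "empirical_p": self.empirical_p,
            "seed": self.seed, "direction": self.direction,
            "n_undefined": self.n_undefined,
        }


@dataclass
class TestResult:
    """Mann-Whitney U with either exact or asymptotic two-sided p."""

    U: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    exact: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"U": self.U, "z": self.z, "p_two_sided": self.p_two_sided,
                "n1": self.n1, "n2": self.n2, "exact": self.exact,
                "degenerate": self.degenerate}


# ------------------------------------------------------------------ bootstrap

def bootstrap_summary(values: Sequence[float], n_boot: int = 1000,
                      seed: int = 0) -> BootstrapSummary:
    """Resample with replacement n_boot times; s.d. of the resampled means."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("bootstrap_summary: empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    return BootstrapSummary(mean=float(arr.mean()),
                            sd_of_means=float(means.std(ddof=0)),
                            n_boot=n_boot, seed=seed)


# ----------------------------------------------------------- permutation null

def _draw_distinct_pairs(rng: np.random.Generator, n_genes: int,
                         n_pairs: int) -> np.ndarray:
    """Uniformly random distinct unordered pairs as an (n_pairs, 2) index array."""
    max_pairs = n_genes * (n_genes - 1) // 2
    if n_pairs > max_pairs:
        raise InputError(f"cannot draw {n_pairs} distinct pairs from {n_genes} genes")
    chosen = np.empty((0,), dtype=np.int64)
    while chosen.size < n_pairs:
        need = n_pairs - chosen.size
        batch = max(int(need * 1.3) + 16, 32)
        i = rng.integers(0, n_genes, size=batch)
        j = rng.integers(0, n_genes, size=batch)
        ok = i != j
        lo = np.minimum(i[ok], j[ok])
        hi = np.maximum(i[ok], j[ok])
        codes = lo * n_genes + hi
        pool = np.concatenate([chosen, codes])
        _, first = np.unique(pool, return_index=True)
        chosen = pool[np.sort(first)][:n_pairs]
    lo, hi = chosen // n_genes, chosen % n_genes
    return np.column_stack([lo, hi])


def permutation_null(
    statistic: Callable[[List[GenePair]], float],
    n_pairs: int,
    gene_universe: Sequence[str],
    n_perm: int,
    seed: int,
    direction: str = "greater",
    observed: Optional[float] = None,
    observed_pairs: Optional[Sequence[GenePair]] = None,
) -> PermutationResult:
    """Permutation null over random distinct gene pairs.

    ``statistic`` maps a list of pairs to a float (NaN when undefined).
    Either ``observed`` or ``observed_pairs`` (from which the observed value
    is computed with the same statistic) must be given. ``direction``
    says which tail counts as at least as extreme.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if direction not in ("greater", "less"):
        raise InputError(f"direction must be 'greater' or 'less', got {direction!r}")
    if observed is None:
        if observed_pairs is None:
            raise InputError("need observed or observed_pairs")
        observed = float(statistic(list(observed_pairs)))
    genes = list(gene_universe)
    rng = np.random.default_rng(seed)
    null_values = np.empty(n_perm)
    for k in range(n_perm):
        idx = _draw_distinct_pairs(rng, len(genes), n_pairs)
        pairs = [(genes[i], genes[j]) for i, j in idx]
        null_values[k] = statistic(pairs)
    defined = null_values[~np.isnan(null_values)]
    n_undefined = n_perm - defined.size
    if defined.size < n_perm / 2:
        raise UndefinedStatistic(
            f"statistic undefined on {n_undefined}/{n_perm} permutation replicates"
        )
    if direction == "greater":
        exceed = int((defined >= observed).sum())
    else:
        exceed = int((defined <= observed).sum())
    n_eff = int(defined.size)
    return PermutationResult(
        observed=observed, n_perm=n_eff,
        null_mean=float(defined.mean()), null_sd=float(defined.std(ddof=0)),
        exceed_count=exceed, empirical_p=(1 + exceed) / (1 + n_eff),
        seed=seed, direction=direction, n_undefined=n_undefined,
    )


# --------------------------------------------------------------- Mann-Whitney

def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U with midranks.

    Exact p by enumeration of the conditional rank distribution when
    n1 + n2 <= 12 (valid under ties as a permutation test); otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise InputError("mann_whitney_u: both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(U=n1 * n2 / 2, z=0.0, p_two_sided=1.0,
                          n1=n1, n2=n2, exact=False, degenerate=True)
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var > 0:
        shift = abs(u - mu) - 0.5
        z = math.copysign(max(shift, 0.0) / math.sqrt(var), u - mu)
    else:
        z = 0.0
    if n <= EXACT_LIMIT:
        dev = abs(u - mu)
        total = 0
        hits = 0
        for subset in combinations(range(n), n1):
            u_perm = float(ranks[list(subset)].sum()) - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
        return TestResult(U=u, z=z, p_two_sided=p, n1=n1, n2=n2, exact=True)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TestResult(U=u, z=z, p_two_sided=p, n1=n1, n2=n2, exact=False)


# ------------------------------------------------------------ relative change

NEW_BASE = "NEW_BASE"
OLD_BASE = "OLD_BASE"


def relative_change(a: float, b: float, convention: str) -> float:
    """Percent change between two summary values.

    NEW_BASE: 100*(a-b)/a (change relative to the new/combined value);
    OLD_BASE: 100*(a-b)/b (change relative to the old/reference value).
    Both conventions occur in published increments, so every reported
    change must carry its convention label.
    """
    if convention == NEW_BASE:
        denom = a
    elif convention == OLD_BASE:
        denom = b
    else:
        raise InputError(f"unknown convention {convention!r}")
    if denom == 0:
        raise UndefinedStatistic(f"relative_change: zero denominator ({convention})")
    return 100.0 * (a - b) / denom
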