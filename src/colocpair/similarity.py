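"""Co-expression fractions and per-mark modification differences.

Per pair class the reported quantities are (1) the fraction of pairs
whose expression profiles correlate at or above a Pearson threshold
(0.5 "high", 0.1 "low") and (2) the mean absolute difference of a per-gene
modification level for one mark. Pairs for which the statistic is
undefined (a gene missing from the matrix, fewer than three shared
conditions, zero variance) are excluded and counted, never treated as
non-co-expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genome import GenePair
from .stats import BootstrapSummary, PermutationResult

MIN_CONDITIONS = 3


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when undefined.

    Positions missing (NaN) in either vector are dropped. The correlation
    is undefined (NaN) when fewer than three shared positions remain or
    either variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("pearson_r: vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_CONDITIONS:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def pair_correlations(pairs: Sequence[GenePair], expr: pd.DataFrame) -> np.ndarray:
    """Pearson r per pair; NaN where undefined or a gene is absent."""
    out = np.full(len(pairs), np.nan)
    index = expr.index
    values = expr.to_numpy(dtype=float)
    loc = {g: i for i, g in enumerate(index)}
    for k, (a, b) in enumerate(pairs):
        ia, ib = loc.get(a), loc.get(b)
        if ia is None or ib is None:
            continue
        out[k] = pearson_r(values[ia], values[ib])
    return out


@dataclass
class ClassSimilarityResult:
    """One observed similarity statistic for one pair class."""

    class_label: str
    statistic: str                  # "coexpr_fraction" or "mean_abs_diff"
    threshold_or_mark: object
    observed: float
    n_pairs_used: int
    n_excluded: int
    bootstrap: Optional[BootstrapSummary] = None
    permutation: Optional[PermutationResult] = None

    def to_dict(self) -> dict:
        d = {
            "class_label": self.class_label,
            "statistic": self.statistic,
            "threshold_or_mark": self.threshold_or_mark,
            "observed": self.observed,
            "n_pairs_used": self.n_pairs_used,
            "n_excluded": self.n_excluded,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict()
        if self.permutation is not None:
            d["permutation"] = self.permutation.to_dict()
        return d


def coexpr_fraction(
    pairs: Sequence[GenePair],
    expr: pd.DataFrame,
    threshold: float,
    *,
    class_label: str = "",
    absolute: bool = False,
) -> ClassSimilarityResult:
    """Fraction of pairs with defined r >= threshold (signed by default).

    ``absolute=True`` compares |r| to the threshold instead; the default is
    the signed rule.
    """
    if not -1.0 < threshold < 1.0:
        raise InputError(f"threshold must be in (-1, 1), got {threshold}")
    r = pair_correlations(pairs, expr)
    defined = ~np.isnan(r)
    n_used = int(defined.sum())
    if n_used == 0:
        raise InputError("coexpr_fraction: no pair has a defined correlation")
    vals = np.abs(r[defined]) if absolute else r[defined]
    frac = float((vals >= threshold).mean())
    return ClassSimilarityResult(
        class_label=class_label, statistic="coexpr_fraction",
        threshold_or_mark=threshold, observed=frac,
        n_pairs_used=n_used, n_excluded=len(pairs) - n_used,
    )


def mod_abs_diff(pairs: Sequence[GenePair], mods: pd.DataFrame, mark: str) -> np.ndarray:
    """|level_a - level_b| per pair with both genes present, for one mark."""
    if mark not in mods.columns:
        raise InputError(f"unknown mark {mark!r}")
    col = mods[mark]
    out = []
    for a, b in pairs:
        if a in col.index and b in col.index:
            va, vb = float(col[a]), float(col[b])
            if not (np.isnan(va) or np.isnan(vb)):
                out.append(abs(va - vb))
    return np.asarray(out)


def class_mod_similarity(
    pairs: Sequence[GenePair],
    mods: pd.DataFrame,
    mark: str,
    *,
    class_label: str = "",
) -> ClassSimilarityResult:
    """Mean |difference| of one mark over a pair class."""
    diffs = mod_abs_diff(pairs, mods, mark)
    if diffs.size == 0:
        raise InputError(f"class {class_label or '<unnamed>'}: no usable pairs for {mark}")
    return ClassSimilarityResult(
        class_label=class_label, statistic="mean_abs_diff",
        threshold_or_mark=mark, observed=float(diffs.mean()),
        n_pairs_used=int(diffs.size), n_excluded=len(pairs) - int(diffs.size),
    )
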