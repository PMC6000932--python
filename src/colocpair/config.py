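"""Configuration objects and the seed-splitting rule.

All randomness flows from one root seed. Each generator / pipeline stage
receives its own child seed from :func:`derive_seeds`, which spawns a
``numpy.random.SeedSequence`` per named stream in a fixed order, so a run
is reproducible end to end and any single stage can be re-run in isolation
from the seeds recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ConfigError

DEFAULT_MARKS: Tuple[str, ...] = (
    "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me2", "H3K14ac", "H3K18ac",
    "H3K23ac", "H3K27ac", "H3K27me1", "H3K27me3", "H3K36ac", "H3K36me2",
    "H3K36me3", "H3K56ac", "H4K16ac", "X5mC",
)


@dataclass(frozen=True)
class ComparatorRates:
    """Per-comparator rearrangement intensity.

    inversions / translocations are event counts per genome; loss_prob is
    the marginal per-gene probability of having no detectable ortholog.
    """

    inversions: int = 400
    translocations: int = 10
    loss_prob: float = 0.85

    def __post_init__(self):
        if self.inversions < 0 or self.translocations < 0:
            raise ConfigError("rearrangement counts must be >= 0")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ConfigError(f"loss_prob must be in [0,1], got {self.loss_prob}")

    def scaled(self, factor: float) -> "ComparatorRates":
        return ComparatorRates(
            inversions=int(round(self.inversions * factor)),
            translocations=int(round(self.translocations * factor)),
            loss_prob=self.loss_prob * factor,
        )


def _default_rates() -> List[ComparatorRates]:
    """One close, two moderately diverged, three distant comparators.

    The close comparator has 10x lower rates than the distant tier
    throughout; the moderate tier sits in between (about half the genes
    still detectable as orthologs, a third of surviving adjacencies broken).
    """
    distant = ComparatorRates(inversions=400, translocations=10, loss_prob=0.85)
    moderate = ComparatorRates(inversions=200, translocations=10, loss_prob=0.50)
    close = distant.scaled(0.1)
    return [close, moderate, moderate, distant, distant, distant]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome-evolution generator.

    The defaults emulate an Arabidopsis-like anchor compared against one
    phylogenetically close and five distant flowering-plant genomes: distant
    comparators keep detectable orthologs for ~30% of genes and are heavily
    rearranged; the close comparator has 10x lower rates throughout.
    """

    n_genes: int = 2000
    n_chromosomes: int = 5
    n_comparators: int = 6
    comparator_rates: List[ComparatorRates] = field(default_factory=_default_rates)
    n_close: int = 1                      # first n_close comparators form the "close" set
    n_interaction_pairs: int = 600
    interaction_decay: float = 2.0        # P(pair) ~ (gene-index distance)^-decay
    n_conditions: int = 50
    planted_corr: float = 0.5             # rho planted on colocalized pairs
    planted_mod_similarity: float = 0.3   # noise s.d. / latent s.d. for planted marks
    planted_marks: Tuple[str, ...] = ("H3K27me3", "X5mC")
    n_marks: int = 16
    marks: Tuple[str, ...] = DEFAULT_MARKS
    loss_run_mean: float = 8.0            # mean length (genes) of a deleted segment
    tandem_dup_prob: float = 0.0          # per-gene tandem duplication (many-to-many)
    gene_length: int = 1000               # bp; cosmetic, adjacency is rank-based
    gene_gap: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_chromosomes", "n_comparators", "n_interaction_pairs",
                     "n_conditions", "n_marks"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_chromosomes > self.n_genes:
            raise ConfigError("n_chromosomes cannot exceed n_genes")
        if not -1.0 <= self.planted_corr <= 1.0:
            raise ConfigError("planted_corr must be in [-1, 1]")
        if not 0.0 < self.planted_mod_similarity <= 1.0:
            raise ConfigError("planted_mod_similarity must be in (0, 1]")
        if self.interaction_decay < 0:
            raise ConfigError("interaction_decay must be >= 0")
        if self.n_marks < 2:
            raise ConfigError("n_marks must be >= 2 (H3K27me3 and X5mC required)")
        if len(self.comparator_rates) != self.n_comparators:
            raise ConfigError(
                f"need {self.n_comparators} comparator_rates entries, "
                f"got {len(self.comparator_rates)}"
            )
        if not 0 <= self.n_close <= self.n_comparators:
            raise ConfigError("n_close must be in [0, n_comparators]")
        if self.loss_run_mean < 1.0:
            raise ConfigError("loss_run_mean must be >= 1")
        if not 0.0 <= self.tandem_dup_prob < 1.0:
            raise ConfigError("tandem_dup_prob must be in [0, 1)")
        marks = tuple(self.marks)[: self.n_marks]
        if len(marks) < self.n_marks:
            raise ConfigError("not enough mark names for n_marks")
        self.marks = marks
        for m in self.planted_marks:
            if m not in self.marks:
                raise ConfigError(f"planted mark {m!r} not among marks")
        if not {"H3K27me3", "X5mC"} <= set(self.marks):
            raise ConfigError("marks must include H3K27me3 and X5mC")

    @property
    def comparator_ids(self) -> List[str]:
        return [f"comp{i + 1:02d}" for i in range(self.n_comparators)]

    @property
    def close_set(self) -> List[str]:
        return self.comparator_ids[: self.n_close]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic mode)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    thresholds: Tuple[float, ...] = (0.5, 0.1)
    marks_of_interest: Tuple[str, ...] = ("H3K27me3", "X5mC")
    n_perm: int = 10_000
    n_boot: int = 1000
    alpha: float = 0.05
    n_no_coloc: int = 500                 # size of the no-colocalization sample
    seed: int = 0
    out_dir: str = "coloc_out"

    def __post_init__(self):
        for t in self.thresholds:
            if not -1.0 < t < 1.0:
                raise ConfigError(f"threshold {t} must be in (-1, 1)")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("n_perm and n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


STREAMS = (
    "anchor", "comparators", "interactions", "planting", "expression",
    "modifications", "no_coloc", "permutation", "bootstrap",
)


def derive_seeds(root_seed: int, streams: Sequence[str] = STREAMS) -> Dict[str, int]:
    """One child seed per named stream, in fixed order, from the root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(streams))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(streams, children)
    }


def load_run_config(path: str) -> RunConfig:
    """Read a RunConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn_raw = raw.pop("synthetic", {})
    rates_raw = syn_raw.pop("comparator_rates", None)
    if rates_raw is not None:
        syn_raw["comparator_rates"] = [ComparatorRates(**r) for r in rates_raw]
    for key in ("marks", "planted_marks"):
        if key in syn_raw:
            syn_raw[key] = tuple(syn_raw[key])
    synthetic = SyntheticConfig(**syn_raw)
    for key in ("thresholds", "marks_of_interest"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(synthetic=synthetic, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def config_to_dict(config: RunConfig) -> dict:
    return asdict(config)
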