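import numpy as np
import pytest

from colocpair import (
    ComparatorRates,
    GeneRecord,
    GenomeAnnotation,
    RunConfig,
    SyntheticConfig,
    classify_all,
    generate_dataset,
)


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two chromosomes: chr1 g1<g2<g3, chr2 g4 alone."""
    return GenomeAnnotation(
        "anchor",
        [
            GeneRecord("g1", "chr1", 100, 200),
            GeneRecord("g2", "chr1", 300, 400),
            GeneRecord("g3", "chr1", 500, 600),
            GeneRecord("g4", "chr2", 100, 200),
        ],
        genome_size=10_000,
    )


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast config for pipeline-shaped tests (not the study conditions)."""
    defaults = dict(
        n_genes=120,
        n_chromosomes=3,
        n_comparators=3,
        comparator_rates=[
            ComparatorRates(inversions=2, translocations=1, loss_prob=0.05),
            ComparatorRates(inversions=10, translocations=2, loss_prob=0.4),
            ComparatorRates(inversions=25, translocations=2, loss_prob=0.7),
        ],
        n_close=1,
        n_interaction_pairs=60,
        n_conditions=20,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset under the study conditions (the package defaults)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_classified(default_dataset):
    ds = default_dataset
    return classify_all(ds.anchor, ds.comparators.values(), ds.orthologs,
                        ds.interactions)


@pytest.fixture(scope="session")
def default_report(tmp_path_factory):
    """Full pipeline run at the acceptance-scale resampling sizes."""
    from colocpair import run_all

    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(n_perm=1000, n_boot=200, seed=1, out_dir=str(out))
    return run_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
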