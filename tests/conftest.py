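import pandas as pd
import pytest

from xreact.classify import classify_genes, load_count_table
from xreact.core import read_gene_table
from xreact.simulate import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down study population for fast tests."""
    base = dict(
        seed=7,
        chrom_length_bp=30_000_000,
        n_genes=400,
        n_informative=150,
        n_escapees=12,
        n_reactivated=30,
        n_above_mecp2=3,
        n_hypomethylated_promoters=6,
        n_tads=30,
        n_tads_enriched=2,
        n_tads_depleted=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full-size synthetic bundle at seed 1 (the paper-default population)."""
    out = tmp_path_factory.mktemp("bundle_seed1")
    bundle, truth = simulate_dataset(SimulationConfig(seed=1), out)
    return bundle, truth


@pytest.fixture(scope="session")
def default_classes(default_bundle):
    """Full classification of the seed-1 bundle."""
    bundle, _ = default_bundle
    genes = read_gene_table(bundle["genes"])
    table = load_count_table(bundle["counts"])
    classes = classify_genes(table, [g.gene_id for g in genes])
    return genes, table, classes


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle_small")
    cfg = small_config()
    bundle, truth = simulate_dataset(cfg, out)
    return cfg, bundle, truth
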