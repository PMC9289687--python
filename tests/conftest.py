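import numpy as np
import pandas as pd
import pytest

from ploidymeth.simulate import (
    SimulationConfig,
    plant_dmrs,
    simulate_genome,
    simulate_methylome,
)


def make_records(rows):
    """Build a cytosine table from (chrom, pos, strand, context, n_meth, n_total)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    ).astype({"pos": np.int64, "n_meth": np.int64, "n_total": np.int64})


def make_features(rows):
    """Build a feature table from (id, chrom, start, end, strand, kind,
    subkind, te_class, te_order)."""
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "start", "end", "strand", "kind",
                 "subkind", "te_class", "te_order"],
    ).astype({"start": np.int64, "end": np.int64})


@pytest.fixture(scope="session")
def small_sim():
    """One 300-kb chromosome with features and a 2x methylome."""
    cfg = SimulationConfig(n_chroms=1, chrom_length=300_000, seed=11)
    genome, features = simulate_genome(cfg, seed=11)
    records = simulate_methylome(genome, features, cfg, "2x", 1, seed=11)
    return cfg, genome, features, records


@pytest.fixture(scope="session")
def dmr_recovery_run():
    """2-Mb genome, 30x depth, 20 planted CG DMRs (delta 0.4, >=10 CG
    sites each), one methylome per cytotype."""
    cfg = SimulationConfig(n_chroms=2, chrom_length=1_000_000, seed=7)
    genome, features = simulate_genome(cfg, seed=7)
    hyper = plant_dmrs(genome, features, "CG", n=10, delta=0.4, min_sites=10,
                       direction="hyper", seed=7)
    hypo = plant_dmrs(genome, features, "CG", n=10, delta=0.4, min_sites=10,
                      direction="hypo", seed=8, avoid=hyper)
    planted = pd.concat([hyper, hypo], ignore_index=True)
    rec2 = simulate_methylome(genome, features, cfg, "2x", 1, seed=7, planted_dmrs=planted)
    rec4 = simulate_methylome(genome, features, cfg, "4x", 1, seed=7, planted_dmrs=planted)
    return cfg, genome, features, planted, rec2, rec4
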