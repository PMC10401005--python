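import numpy as np
import pytest

from panpav import (
    SimulationConfig,
    simulate_guide_tree,
    simulate_pav,
)


@pytest.fixture(scope="session")
def small_panel():
    """A 3-clade x 6-accession panel with defaults scaled down: the shared
    substrate for statistics and clustering tests."""
    cfg = SimulationConfig(
        seed=11,
        n_clades=3,
        accessions_per_clade=6,
        n_core_genes=300,
        n_shell_genes=400,
        n_cloud_genes=60,
        # bonus scaled with the gene universe (defaults assume 5,000 genes)
        ploidy_gene_bonus=15.0,
    )
    tree = simulate_guide_tree(cfg.n_clades, cfg.accessions_per_clade, seed=cfg.seed)
    pav, truth = simulate_pav(tree, cfg)
    return cfg, pav, truth


@pytest.fixture(scope="session")
def noise_free_panel():
    """Small panel with all noise off and no ploidy inflation: the exact
    closure fixture (PAV calls from simulated coverage must equal truth)."""
    cfg = SimulationConfig(
        seed=7,
        n_clades=2,
        accessions_per_clade=4,
        n_core_genes=80,
        n_shell_genes=120,
        n_cloud_genes=30,
        noise_fp=0.0,
        noise_fn=0.0,
        ploidy_gene_bonus=0.0,
    )
    tree = simulate_guide_tree(cfg.n_clades, cfg.accessions_per_clade, seed=cfg.seed)
    pav, truth = simulate_pav(tree, cfg)
    return cfg, pav, truth


def brute_force_uncovered_runs(length, covered, min_len):
    """Per-base oracle for unaligned-region extraction: mark covered bases,
    return maximal uncovered runs of at least min_len."""
    mask = np.zeros(length, dtype=bool)
    for s, e in covered:
        mask[s:e] = True
    runs = []
    start = None
    for i in range(length):
        if not mask[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_len:
                    runs.append((start, i))
                start = None
    if start is not None and length - start >= min_len:
        runs.append((start, length))
    return runs
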