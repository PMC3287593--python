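import numpy as np
import pytest

from ceqtl.cgh_processing import (
    fit_bimodal_modes,
    normalize_dosage,
    sliding_window_smooth,
)
from ceqtl.genome import uniform_genome
from ceqtl.synthetic_panel import (
    SimulationConfig,
    plant_effects,
    simulate_acgh,
    simulate_expression,
    simulate_fragments,
)


@pytest.fixture(scope="session")
def small_genome():
    """3 autosomes + X, 150 kb marker spacing, 80 genes."""
    return uniform_genome(
        [
            ("chr1", 90_000_000, "autosome"),
            ("chr2", 90_000_000, "autosome"),
            ("chr3", 90_000_000, "autosome"),
            ("chrX", 90_000_000, "sex"),
        ],
        marker_spacing=150_000,
        n_genes=80,
        centromeres={"chr1": (40_000_000, 44_000_000), "chr2": (40_000_000, 44_000_000)},
        seed=11,
    )


def build_panel(genome, config):
    """simulate -> smooth -> fit modes -> normalize -> expression."""
    truth = simulate_fragments(genome, config)
    truth = plant_effects(truth, genome, config)
    raw = simulate_acgh(truth, genome, config)
    smoothed = sliding_window_smooth(raw)
    modes = fit_bimodal_modes(smoothed.values.ravel())
    normalized = normalize_dosage(smoothed, modes)
    expr = simulate_expression(truth, normalized, genome, config)
    return truth, raw, normalized, expr


@pytest.fixture(scope="session")
def noiseless_panel(small_genome):
    config = SimulationConfig(n_clones=79, acgh_noise_sd=0.0, expr_noise_sd=0.0, seed=5)
    return (config,) + build_panel(small_genome, config)


@pytest.fixture(scope="session")
def noisy_panel(small_genome):
    config = SimulationConfig(n_clones=79, acgh_noise_sd=0.03, expr_noise_sd=0.05, seed=7)
    return (config,) + build_panel(small_genome, config)


def nearest_marker_fit(genome, normalized, expr, truth):
    """Planted vs refit alpha at each gene's nearest marker (skips constant x)."""
    from ceqtl.ceqtl_mapping import fit_dosage_model

    planted, estimated, gene_ids = [], [], []
    for i, g in enumerate(genome.genes):
        mid = (g.start + g.end) // 2
        r = genome.nearest_marker_index(g.chrom, mid)
        try:
            fit = fit_dosage_model(expr.values[i], normalized.values[r])
        except ValueError:
            continue
        planted.append(truth.gene_alpha[g.gene_id])
        estimated.append(fit.alpha)
        gene_ids.append(g.gene_id)
    return np.array(planted), np.array(estimated), gene_ids
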