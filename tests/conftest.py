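import numpy as np
import pandas as pd
import pytest

from invadomics import screen, simulate


@pytest.fixture(scope="session")
def small_screen():
    """A 100-gene screen with a strong planted depletion (seed 1)."""
    cfg = simulate.ScreenSimConfig(
        n_genes=100, guides_per_gene=5, n_nontargeting=50,
        frac_essential=0.1, effect_log2=-2.0, dispersion=0.2,
        mean_depth=500, seed=1)
    counts, truth = simulate.simulate_screen_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def small_screen_scores(small_screen):
    _, counts, truth = small_screen
    fit = screen.guide_fitness(screen.pool_and_normalize(counts))
    return screen.gene_score(fit), truth


@pytest.fixture()
def toy_counts():
    """Two guides, one nontargeting, two samples per fraction."""
    return pd.DataFrame({
        "guide_id": ["g1", "g2", "ntc1"],
        "gene": ["A", "B", "NTC"],
        "is_nontargeting": [False, False, True],
        "core_1": [1, 9, 5],
        "core_2": [9, 81, 45],
        "invasive_1": [5, 5, 5],
        "invasive_2": [45, 45, 45],
    })


@pytest.fixture(scope="session")
def spheroid_field_mask():
    """Spheroid core + paired background cells + 3 pinned isolated cells."""
    cfg = simulate.MaskSimConfig(
        shape_kind="spheroid_field", image_size=256, radius=40, n_cells=20,
        detached_positions_um=((200.0, 40.0), (220.0, 200.0), (40.0, 220.0)),
        seed=3)
    return simulate.simulate_mask(cfg), cfg


def brute_force_detached(cells, radius_um=10.0):
    """O(n^2) oracle for the nearest-neighbour detachment rule."""
    out = []
    for i, c in enumerate(cells):
        d = [np.hypot(c.centroid[0] - o.centroid[0], c.centroid[1] - o.centroid[1])
             for j, o in enumerate(cells) if j != i]
        if not d or min(d) > radius_um:
            out.append(c)
    return out
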