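import numpy as np
import pytest

from lupings.simulate import (
    SimulationConfig,
    simulate_factorial_cross_population,
    simulate_trait_architecture,
)
from lupings.trial import PlotObservation, SOIL_TYPES, WATER_LEVELS


@pytest.fixture
def tiny_config():
    return SimulationConfig(seed=11, n_markers=120)


@pytest.fixture
def small_lines(tiny_config):
    """80 inbred lines from a 4 x 4 factorial cross, 120 markers."""
    return simulate_factorial_cross_population(tiny_config, lines_per_cross=5)


@pytest.fixture
def yield_architecture(tiny_config):
    return simulate_trait_architecture(tiny_config, "grain_yield")


def make_balanced_plots(
    n_genotypes: int = 4,
    n_blocks: int = 2,
    seed: int = 0,
    genotype_effects=None,
    water_effects=None,
    gw_effects=None,
    noise_sd: float = 1.0,
    mean: float = 5.0,
    trait: str = "y",
):
    """Balanced g x 2 x 2 x r dataset with optional planted effects."""
    rng = np.random.default_rng(seed)
    ge = np.zeros(n_genotypes) if genotype_effects is None else np.asarray(genotype_effects)
    we = {"drought": 0.0, "favorable": 0.0} if water_effects is None else water_effects
    gw = (
        np.zeros((n_genotypes, 2))
        if gw_effects is None
        else np.asarray(gw_effects)
    )
    plots = []
    for g in range(n_genotypes):
        for wi, water in enumerate(WATER_LEVELS):
            for soil in SOIL_TYPES:
                for b in range(1, n_blocks + 1):
                    value = (
                        mean
                        + ge[g]
                        + we[water]
                        + gw[g, wi]
                        + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    )
                    plots.append(
                        PlotObservation(
                            genotype_id=f"G{g + 1}",
                            water=water,
                            soil=soil,
                            block=b,
                            traits={trait: float(value)},
                        )
                    )
    return plots


def projection_anova_ss(df):
    """Independent sequential-projection ANOVA oracle for the balanced design.

    Builds raw dummy design matrices term by term and takes differences of
    least-squares residual sums of squares — a code path sharing nothing
    with the cell-mean decomposition under test.
    """

    def dummies(values):
        levels = sorted(set(values))
        return np.column_stack([(values == lev).astype(float) for lev in levels])

    env = df["water"].astype(str) + "/" + df["soil"].astype(str)
    blk = env + "/b" + df["block"].astype(str)
    g = dummies(df["genotype"].to_numpy())
    w = dummies(df["water"].to_numpy())
    s = dummies(df["soil"].to_numpy())
    e = dummies(env.to_numpy())
    bl = dummies(blk.to_numpy())

    def interact(a, b):
        return np.column_stack(
            [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
        )

    y = df["value"].to_numpy(dtype=float)
    terms = [
        ("genotype", g),
        ("water", w),
        ("soil", s),
        ("water_x_soil", e),
        ("block(environment)", bl),
        ("genotype_x_water", interact(g, w)),
        ("genotype_x_soil", interact(g, s)),
        ("genotype_x_water_x_soil", interact(g, e)),
    ]
    X = np.ones((len(y), 1))
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss_prev = float(np.sum((y - X @ beta) ** 2))
    out = {}
    for name, cols in terms:
        X = np.column_stack([X, cols])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        out[name] = rss_prev - rss
        rss_prev = rss
    out["residual"] = rss_prev
    return out
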