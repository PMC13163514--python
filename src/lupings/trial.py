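"""Managed-environment trial analytics.

The validation experiment behind this module is a 2 x 2 factorial of water
treatment (moderate terminal drought vs. moisture-favorable) and soil type
(sandy-loam non-calcareous vs. silty-clay moderately calcareous), laid out as
a randomized complete block design with ``r`` blocks nested within each of
the four managed environments.  The module provides:

* water-budget accounting for the stress vs. favorable irrigation regimes,
* plot-level derived traits (harvest index, plant density),
* balanced factorial ANOVA partitioning the environment term into water
  amount, soil type and their interaction, with block-within-environment as
  the error term for those whole-plot factors,
* LSD mean separation with letter groupings, and
* detection of crossover genotype x environment interaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WATER_LEVELS",
    "SOIL_TYPES",
    "PlotObservation",
    "WaterBudget",
    "MeanComparison",
    "plots_to_frame",
    "frame_to_plots",
    "water_reduction_pct",
    "harvest_index",
    "plant_density",
    "lsd_value",
    "anova_partitioned",
    "environment_means",
    "stress_reduction_pct",
    "detect_crossover",
]

WATER_LEVELS = ("drought", "favorable")
SOIL_TYPES = ("sandy_loam", "silty_clay")


@dataclass
class PlotObservation:
    """Trait records for one field plot.

    ``traits`` maps trait name to value (e.g. grain yield and straw biomass
    in t/ha, flowering and maturity time in days, plant height in cm,
    individual seed weight in g, harvest index as a fraction).
    """

    genotype_id: str
    water: str
    soil: str
    block: int
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.water not in WATER_LEVELS:
            raise ValueError(f"unknown water level {self.water!r}")
        if self.soil not in SOIL_TYPES:
            raise ValueError(f"unknown soil type {self.soil!r}")
        for name in ("grain_yield", "straw_biomass"):
            if name in self.traits and self.traits[name] < 0:
                raise ValueError(f"{name} must be non-negative")
        hi = self.traits.get("harvest_index")
        if hi is not None and not (0.0 <= hi <= 1.0):
            raise ValueError("harvest index must lie in [0, 1]")

    @property
    def environment(self) -> str:
        return f"{self.water}/{self.soil}"


def plots_to_frame(plots: list[PlotObservation]) -> pd.DataFrame:
    """Tidy long-format table: genotype, water, soil, block, trait, value."""
    rows = [
        (p.genotype_id, p.water, p.soil, p.block, trait, value)
        for p in plots
        for trait, value in p.traits.items()
    ]
    return pd.DataFrame(
        rows, columns=["genotype", "water", "soil", "block", "trait", "value"]
    )


def frame_to_plots(df: pd.DataFrame) -> list[PlotObservation]:
    """Inverse of :func:`plots_to_frame`."""
    required = {"genotype", "water", "soil", "block", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    plots = []
    keys = ["genotype", "water", "soil", "block"]
    for (gid, water, soil, block), grp in df.groupby(keys, sort=False):
        plots.append(
            PlotObservation(
                genotype_id=str(gid),
                water=water,
                soil=soil,
                block=int(block),
                traits=dict(zip(grp["trait"], grp["value"].astype(float))),
            )
        )
    return plots


# ---------------------------------------------------------------------------
# water budgets and plot-level derived quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterBudget:
    """Water amounts (mm) for one managed-environment pair.

    ``before_sowing`` (BS) and ``sowing_to_application`` (SA) are common to
    both treatments; ``during_stress`` (DS) and ``during_favorable`` (MF) are
    the amounts received during treatment application by the drought-stress
    and moisture-favorable regimes respectively.
    """

    before_sowing: float
    sowing_to_application: float
    during_stress: float
    during_favorable: float

    def __post_init__(self) -> None:
        for name in (
            "before_sowing",
            "sowing_to_application",
            "during_stress",
            "during_favorable",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_stress(self) -> float:
        return self.before_sowing + self.sowing_to_application + self.during_stress

    @property
    def total_favorable(self) -> float:
        return self.before_sowing + self.sowing_to_application + self.during_favorable


def water_reduction_pct(budget: WaterBudget) -> int:
    """Percent reduction in total water of the stress vs. favorable regime.

    Computed as ``100 * (1 - (BS + SA + DS) / (BS + SA + MF))``, rounded to
    the nearest integer.
    """
    total_fav = budget.total_favorable
    if total_fav <= 0:
        raise ValueError("favorable-treatment total water must be positive")
    return round(100.0 * (1.0 - budget.total_stress / total_fav))


def harvest_index(grain: float, straw: float) -> float:
    """Grain dry weight over total above-ground dry weight, per plot."""
    if grain < 0 or straw < 0:
        raise ValueError("grain and straw weights must be non-negative")
    total = grain + straw
    if total == 0:
        raise ValueError("grain + straw must be positive")
    return grain / total


def plant_density(
    rows: int = 6,
    row_spacing_m: float = 0.15,
    plants_per_row: int = 4,
    plant_spacing_m: float = 0.20,
    plot_w_m: float = 0.90,
    plot_l_m: float = 0.80,
) -> int:
    """Plants per square metre of plot area, rounded to the nearest integer.

    Defaults describe a 0.90 m x 0.80 m plot of six rows spaced 0.15 m with
    four plants per row spaced 0.20 m (33 plants/m2).
    """
    if min(rows, plants_per_row) <= 0:
        raise ValueError("row and plant counts must be positive")
    if min(row_spacing_m, plant_spacing_m, plot_w_m, plot_l_m) <= 0:
        raise ValueError("plot dimensions must be positive")
    return round(rows * plants_per_row / (plot_w_m * plot_l_m))


# ---------------------------------------------------------------------------
# balanced factorial ANOVA
# ---------------------------------------------------------------------------


def _pivot_balanced(plots: list[PlotObservation], trait: str) -> np.ndarray:
    """Stack plot values into a (genotype, water, soil, block) array.

    Raises if the design is not a complete balanced g x 2 x 2 x r layout
    with exactly one observation per cell.
    """
    df = plots_to_frame(plots)
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    genotypes = sorted(df["genotype"].unique())
    blocks = sorted(df["block"].unique())
    shape = (len(genotypes), len(WATER_LEVELS), len(SOIL_TYPES), len(blocks))
    cube = np.full(shape, np.nan)
    gidx = {g: i for i, g in enumerate(genotypes)}
    widx = {w: i for i, w in enumerate(WATER_LEVELS)}
    sidx = {s: i for i, s in enumerate(SOIL_TYPES)}
    bidx = {b: i for i, b in enumerate(blocks)}
    for rec in df.itertuples():
        cell = (gidx[rec.genotype], widx[rec.water], sidx[rec.soil], bidx[rec.block])
        if not np.isnan(cube[cell]):
            raise ValueError(
                f"duplicate observation for cell {rec.genotype}/{rec.water}/"
                f"{rec.soil}/block {rec.block}"
            )
        cube[cell] = rec.value
    if np.isnan(cube).any():
        g, w, s, b = np.argwhere(np.isnan(cube))[0]
        raise ValueError(
            "unbalanced design: missing cell "
            f"{genotypes[g]}/{WATER_LEVELS[w]}/{SOIL_TYPES[s]}/block {blocks[b]}"
        )
    cube_genotypes = genotypes
    _pivot_balanced.last_genotypes = cube_genotypes  # type: ignore[attr-defined]
    return cube


def anova_partitioned(plots: list[PlotObservation], trait: str) -> pd.DataFrame:
    """Balanced factorial ANOVA with the environment term partitioned.

    Model: genotype, water amount, soil type (fixed) and block nested within
    environment (random), with the environment main effect and its genotype
    interaction split into water, soil and water x soil components.  Water,
    soil and their interaction are tested against the block-within-environment
    mean square; genotype and every genotype-involving interaction are tested
    against the residual.

    Returns a DataFrame indexed by source with columns ``df, ss, ms, F, p,
    error_term``; the last row is the total.
    """
    cube = _pivot_balanced(plots, trait)  # (g, 2, 2, r)
    g, nw, ns, r = cube.shape
    grand = cube.mean()

    m_g = cube.mean(axis=(1, 2, 3))
    m_w = cube.mean(axis=(0, 2, 3))
    m_s = cube.mean(axis=(0, 1, 3))
    m_ws = cube.mean(axis=(0, 3))          # (2, 2)
    m_gw = cube.mean(axis=(2, 3))          # (g, 2)
    m_gs = cube.mean(axis=(1, 3))          # (g, 2)
    m_gws = cube.mean(axis=3)              # (g, 2, 2)
    m_wsb = cube.mean(axis=0)              # (2, 2, r)  block means within env

    ss_g = nw * ns * r * np.sum((m_g - grand) ** 2)
    ss_w = g * ns * r * np.sum((m_w - grand) ** 2)
    ss_s = g * nw * r * np.sum((m_s - grand) ** 2)
    ss_ws = g * r * np.sum(
        (m_ws - m_w[:, None] - m_s[None, :] + grand) ** 2
    )
    ss_block = g * np.sum((m_wsb - m_ws[:, :, None]) ** 2)
    ss_gw = ns * r * np.sum(
        (m_gw - m_g[:, None] - m_w[None, :] + grand) ** 2
    )
    ss_gs = nw * r * np.sum(
        (m_gs - m_g[:, None] - m_s[None, :] + grand) ** 2
    )
    dev3 = (
        m_gws
        - m_gw[:, :, None]
        - m_gs[:, None, :]
        - m_ws[None, :, :]
        + m_g[:, None, None]
        + m_w[None, :, None]
        + m_s[None, None, :]
        - grand
    )
    ss_gws = r * np.sum(dev3**2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_resid = ss_total - (
        ss_g + ss_w + ss_s + ss_ws + ss_block + ss_gw + ss_gs + ss_gws
    )
    ss_resid = max(ss_resid, 0.0)

    n_env = nw * ns
    df_map = {
        "genotype": g - 1,
        "water": nw - 1,
        "soil": ns - 1,
        "water_x_soil": (nw - 1) * (ns - 1),
        "block(environment)": n_env * (r - 1),
        "genotype_x_water": (g - 1) * (nw - 1),
        "genotype_x_soil": (g - 1) * (ns - 1),
        "genotype_x_water_x_soil": (g - 1) * (nw - 1) * (ns - 1),
    }
    ss_map = {
        "genotype": ss_g,
        "water": ss_w,
        "soil": ss_s,
        "water_x_soil": ss_ws,
        "block(environment)": ss_block,
        "genotype_x_water": ss_gw,
        "genotype_x_soil": ss_gs,
        "genotype_x_water_x_soil": ss_gws,
    }
    df_resid = (g * nw * ns * r - 1) - sum(df_map.values())
    df_map["residual"] = df_resid
    ss_map["residual"] = ss_resid

    ms = {k: (ss_map[k] / df_map[k] if df_map[k] > 0 else np.nan) for k in df_map}
    error_for = {
        "water": "block(environment)",
        "soil": "block(environment)",
        "water_x_soil": "block(environment)",
        "genotype": "residual",
        "genotype_x_water": "residual",
        "genotype_x_soil": "residual",
        "genotype_x_water_x_soil": "residual",
    }

    rows = []
    for source, dof in df_map.items():
        err = error_for.get(source)
        if err is not None and ms[err] > 0:
            fval = ms[source] / ms[err]
            pval = sps.f.sf(fval, dof, df_map[err])
        else:
            fval, pval = np.nan, np.nan
        rows.append((source, dof, ss_map[source], ms[source], fval, pval, err or ""))
    rows.append(("total", g * nw * ns * r - 1, ss_total, np.nan, np.nan, np.nan, ""))
    table = pd.DataFrame(
        rows, columns=["source", "df", "ss", "ms", "F", "p", "error_term"]
    ).set_index("source")
    return table


def lsd_value(
    ms_error: float, df_error: int, n_per_mean: int, alpha: float = 0.05
) -> float:
    """Least significant difference between two means at level ``alpha``.

    ``n_per_mean`` is the number of plots averaged into each compared mean,
    e.g. ``r * 2`` for genotype means taken across two soil types with ``r``
    blocks per environment.
    """
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    if df_error < 1:
        raise ValueError("df_error must be at least 1")
    if n_per_mean < 1:
        raise ValueError("n_per_mean must be at least 1")
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(tcrit * np.sqrt(2.0 * ms_error / n_per_mean))


# ---------------------------------------------------------------------------
# mean comparison / LSD letters
# ---------------------------------------------------------------------------


@dataclass
class MeanComparison:
    """Level means with LSD mean-separation letters (descending means)."""

    means: pd.Series
    lsd: float
    letters: dict[str, str]
    n_per_mean: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        out = self.means.sort_values(ascending=False).to_frame("mean")
        out["letters"] = [self.letters[i] for i in out.index]
        return out


def lsd_letters(means: pd.Series, lsd: float) -> dict[str, str]:
    """Assign compact letter groupings given an LSD threshold.

    Two levels share a letter iff their means differ by less than the LSD
    (a difference of exactly the LSD counts as significant).  Letters are
    assigned by a descending-mean sweep over maximal homogeneous runs.
    """
    order = means.sort_values(ascending=False)
    n = len(order)
    intervals: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        # exactly equal means always share a letter, even at LSD = 0
        while j + 1 < n and (
            order.iloc[i] - order.iloc[j + 1] < lsd
            or order.iloc[i] == order.iloc[j + 1]
        ):
            j += 1
        # keep only maximal homogeneous runs
        if not intervals or j > intervals[-1][1]:
            intervals.append((i, j))
    letters: dict[str, str] = {lvl: "" for lvl in order.index}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (lo, hi) in zip(alphabet, intervals):
        for idx in range(lo, hi + 1):
            letters[order.index[idx]] += letter
    return letters


def environment_means(plots: list[PlotObservation], trait: str) -> MeanComparison:
    """Means of the four managed environments, with LSD letter groupings.

    The LSD uses the block-within-environment mean square as the error term
    (the declared error for whole-plot environment contrasts) with
    ``n_per_mean = g * r`` plots per environment mean.
    """
    table = anova_partitioned(plots, trait)
    cube = _pivot_balanced(plots, trait)
    g, _, _, r = cube.shape
    env_means = {}
    for (wi, water), (si, soil) in itertools.product(
        enumerate(WATER_LEVELS), enumerate(SOIL_TYPES)
    ):
        env_means[f"{water}/{soil}"] = float(cube[:, wi, si, :].mean())
    means = pd.Series(env_means)
    ms_err = table.loc["block(environment)", "ms"]
    df_err = int(table.loc["block(environment)", "df"])
    lsd = lsd_value(ms_err, df_err, n_per_mean=g * r)
    return MeanComparison(
        means=means, lsd=lsd, letters=lsd_letters(means, lsd), n_per_mean=g * r
    )


def stress_reduction_pct(env_means, axis: str) -> int:
    """Percent trait reduction along one stress axis of the 2 x 2 factorial.

    ``axis='water'`` contrasts the two drought-stress environment means
    (averaged over soils) against the two moisture-favorable ones;
    ``axis='soil'`` contrasts silty-clay (moderately calcareous) against
    sandy-loam.  Result is ``round(100 * (1 - stressed / favorable))``.
    """
    means = env_means.means if isinstance(env_means, MeanComparison) else env_means
    expected = {f"{w}/{s}" for w in WATER_LEVELS for s in SOIL_TYPES}
    if set(means.index) != expected:
        raise ValueError(f"need exactly the four environment means {sorted(expected)}")
    if axis == "water":
        stressed = means[[f"drought/{s}" for s in SOIL_TYPES]].mean()
        favorable = means[[f"favorable/{s}" for s in SOIL_TYPES]].mean()
    elif axis == "soil":
        stressed = means[[f"{w}/silty_clay" for w in WATER_LEVELS]].mean()
        favorable = means[[f"{w}/sandy_loam" for w in WATER_LEVELS]].mean()
    else:
        raise ValueError("axis must be 'water' or 'soil'")
    if favorable == 0:
        raise ValueError("favorable-level mean is zero")
    return round(100.0 * (1.0 - stressed / favorable))


def detect_crossover(
    means: pd.DataFrame, lsd
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Find significant crossover genotype pairs across two conditions.

    ``means`` is a genotypes x 2-conditions table of trait means; ``lsd``
    is a scalar or a per-condition mapping of least significant differences.
    A pair is a crossover iff the sign of their mean difference reverses
    between the two conditions and the absolute difference reaches the LSD
    in both.
    """
    if means.shape[1] != 2:
        raise ValueError("means must have exactly two condition columns")
    c1, c2 = means.columns
    if np.isscalar(lsd):
        lsd1 = lsd2 = float(lsd)
    else:
        lsd1, lsd2 = float(lsd[c1]), float(lsd[c2])
    found = []
    ids = list(means.index)
    for a, b in itertools.combinations(ids, 2):
        d1 = means.loc[a, c1] - means.loc[b, c1]
        d2 = means.loc[a, c2] - means.loc[b, c2]
        if d1 * d2 < 0 and abs(d1) >= lsd1 and abs(d2) >= lsd2:
            found.append(((a, b), (c1, c2)))
    return found
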