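"""Synthetic breeding populations, trait architectures and trial data.

Generates data with the statistical structure the downstream analysis
assumes, so the whole pipeline (QC -> prediction -> selection -> trial
analysis) is testable without any external download:

* an F6 inbred-line population from a 4 x 4 factorial mating design between
  two parent groups (about 45 lines per cross -> ~720 lines), developed by
  single-seed descent so residual per-locus heterozygosity halves each
  selfing generation;
* a landrace collection of 113 accessions with four inbred genotypes drawn
  per accession (452 genotypes), sharing accession-level allele frequencies
  under a Balding-Nichols drift model;
* sparse additive trait architectures, with flowering time dominated by a
  small number of major genes;
* plot-level data for a 2 water x 2 soil factorial of managed environments
  in randomized complete blocks, with genotype x environment interaction
  including implanted crossover pairs, and environment effects calibrated so
  synthetic grain yields sit on the scale of a real white lupin validation
  trial (grand mean ~3.5 t/ha);
* GBS-style noise: per-marker and per-genotype missingness plus
  heterozygous miscalls, with optional planted defects that exceed the
  standard QC thresholds.

All randomness flows from a single integer seed through named sub-streams,
so identical configurations give identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .trial import PlotObservation, SOIL_TYPES, WATER_LEVELS

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "TRAIT_BASELINES",
    "stream",
    "simulate_factorial_cross_population",
    "simulate_landrace_collection",
    "simulate_trait_architecture",
    "correlated_architecture",
    "simulate_genotype_means",
    "simulate_trial",
    "add_gbs_noise",
]


# Trait scale calibration: (population mean, genetic SD) in trait units.
# Grain yield and straw are in t/ha, flowering/maturity in days from 1 April,
# height in cm, individual seed weight in g, lime susceptibility on a 1-9
# visual score.  Means match a managed-environment white lupin trial grand
# mean; genetic SDs are plausible for the germplasm, not estimates of it.
TRAIT_BASELINES: dict[str, tuple[float, float]] = {
    "grain_yield": (3.53, 0.45),
    "straw_biomass": (4.13, 0.55),
    "flowering_time": (15.95, 1.5),
    "maturity_time": (82.8, 2.0),
    "plant_height": (93.9, 8.0),
    "seed_weight": (0.33, 0.035),
    "lime_susceptibility": (5.0, 1.2),
}

# Environment effect decomposition per trait: deviation added under drought
# (negated under favorable), under sandy-loam (negated under silty-clay),
# and the water x soil interaction deviation (positive for drought/sandy and
# favorable/silty cells).  Calibrated to the 2 x 2 environment means of the
# validation trial.
ENV_EFFECTS: dict[str, tuple[float, float, float]] = {
    "grain_yield": (-0.375, 0.465, 0.055),
    "straw_biomass": (-0.6875, 0.6325, 0.2575),
    "flowering_time": (-0.25, -0.05, 0.05),
    "maturity_time": (-3.0, -3.75, 0.75),
    "plant_height": (-6.5, 11.7, 3.4),
    "seed_weight": (0.0, 0.0, 0.0),
    "lime_susceptibility": (0.0, -1.0, 0.0),
}

_DEFAULT_H2 = {
    "grain_yield": 0.5,
    "straw_biomass": 0.5,
    "flowering_time": 0.8,
    "maturity_time": 0.7,
    "plant_height": 0.6,
    "seed_weight": 0.8,
    "lime_susceptibility": 0.5,
}

_DEFAULT_QTL = {
    "grain_yield": 60,
    "straw_biomass": 60,
    "flowering_time": 10,
    "maturity_time": 30,
    "plant_height": 40,
    "seed_weight": 30,
    "lime_susceptibility": 40,
}


def stream(seed: int, label: str) -> np.random.Generator:
    """Named deterministic sub-stream of a single integer seed."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic study.

    Noise magnitudes (``gei_sd_*``, ``block_sd``, ``plot_error_sd``) are
    expressed in units of each trait's genetic SD so one setting scales
    coherently across traits.  ``plot_error_sd=None`` derives the plot error
    from the target heritability so that genotype means over ``n_blocks``
    replicates realize it; set it explicitly (e.g. 0) to override.
    """

    seed: int = 1
    n_markers: int = 1000
    n_chromosomes: int = 25
    qtl_count: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_QTL))
    major_gene_count: int = 2
    heritability: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_H2))
    gei_sd_water: float = 0.15
    gei_sd_soil: float = 0.15
    gei_sd_interaction: float = 0.05
    crossover_pairs: int = 2
    block_sd: float = 0.3
    plot_error_sd: float | None = None
    n_blocks: int = 4
    missing_rate_marker_range: tuple[float, float] = (0.0, 0.2)
    missing_rate_genotype_range: tuple[float, float] = (0.0, 0.15)
    het_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.n_markers <= 0 or self.n_chromosomes <= 0 or self.n_blocks <= 0:
            raise ValueError("counts must be positive")
        if self.major_gene_count < 0 or self.crossover_pairs < 0:
            raise ValueError("counts must be non-negative")
        for trait, h2 in self.heritability.items():
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"heritability for {trait} must lie in (0, 1]")
        for name in ("missing_rate_marker_range", "missing_rate_genotype_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi < 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi < 1")
        if not 0.0 <= self.het_rate < 1.0:
            raise ValueError("het_rate must lie in [0, 1)")
        for name in ("gei_sd_water", "gei_sd_soil", "gei_sd_interaction", "block_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def h2_for(self, trait: str) -> float:
        return self.heritability.get(trait, 0.5)

    def qtl_for(self, trait: str) -> int:
        return self.qtl_count.get(trait, 40)

    def plot_sd_for(self, trait: str) -> float:
        """Plot-error SD in trait units (derived from h2 unless overridden)."""
        _, sd_g = TRAIT_BASELINES[trait]
        if self.plot_error_sd is not None:
            return self.plot_error_sd * sd_g
        h2 = self.h2_for(trait)
        return sd_g * np.sqrt(self.n_blocks * (1.0 - h2) / h2)


@dataclass
class TraitArchitecture:
    """Sparse additive genetic architecture for one trait."""

    trait: str
    effects: np.ndarray
    qtl_indices: np.ndarray
    major_indices: np.ndarray

    def genetic_values(self, geno: GenotypeMatrix) -> np.ndarray:
        """Raw additive genetic values (mean-centered dosages x effects)."""
        if geno.n_markers != len(self.effects):
            raise ValueError(
                f"architecture spans {len(self.effects)} markers but matrix has "
                f"{geno.n_markers}; genetic values require the full marker panel"
            )
        centered = geno.dosage - geno.dosage.mean(axis=0)
        return centered @ self.effects


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def simulate_factorial_cross_population(
    config: SimulationConfig,
    n_parents_a: int = 4,
    n_parents_b: int = 4,
    lines_per_cross: int = 45,
    inbreeding_generations: int = 5,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Inbred lines from a factorial mating design between two parent groups.

    Each of ``n_parents_a`` parents is crossed with each of ``n_parents_b``,
    and ``lines_per_cross`` lines per cross are advanced by single-seed
    descent for ``inbreeding_generations`` selfing generations (F1 -> F6 at
    the default 5).  Founder parents are fully homozygous with independent
    per-locus allele frequencies drawn Uniform(0.1, 0.9); loci segregate
    independently.  Residual heterozygosity at loci polymorphic within a
    cross is (1/2)^generations in expectation.
    """
    if min(n_parents_a, n_parents_b, lines_per_cross) <= 0:
        raise ValueError("parent and line counts must be positive")
    if inbreeding_generations < 0:
        raise ValueError("inbreeding_generations must be non-negative")
    rng = rng or stream(config.seed, "factorial_cross")
    m = config.n_markers
    p = rng.uniform(0.1, 0.9, size=m)
    parents_a = (rng.random((n_parents_a, m)) < p).astype(int)
    parents_b = (rng.random((n_parents_b, m)) < p).astype(int)

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    for i in range(n_parents_a):
        for j in range(n_parents_b):
            cross = f"A{i + 1}xB{j + 1}"
            a, b = parents_a[i], parents_b[j]
            state = np.where(a == b, 2 * a, 1)[None, :].repeat(lines_per_cross, axis=0)
            state = state.astype(np.int8)
            for _ in range(inbreeding_generations):
                het = state == 1
                draw = rng.random(state.shape)
                state = np.where(het & (draw < 0.25), 0, state)
                state = np.where(het & (draw >= 0.75), 2, state)
            blocks.append(state)
            ids.extend(f"{cross}_{k + 1:03d}" for k in range(lines_per_cross))
            labels.extend([cross] * lines_per_cross)
    chrom, pos = _marker_map(config)
    return GenotypeMatrix(
        genotype_ids=ids,
        marker_ids=[f"M{k + 1:05d}" for k in range(m)],
        dosage=np.vstack(blocks).astype(float),
        chrom=chrom,
        pos=pos,
        cross_labels=labels,
    )


def simulate_landrace_collection(
    config: SimulationConfig,
    n_accessions: int = 113,
    genotypes_per_accession: int = 4,
    fst: float = 0.3,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Inbred genotypes sampled from a structured landrace collection.

    Accession allele frequencies drift from a common base frequency under a
    Balding-Nichols Beta model with differentiation ``fst``; the genotypes
    extracted from one accession share its frequency vector, so
    within-accession genetic distance is smaller than between-accession
    distance on average.  Genotypes are fully homozygous (selfing crop).
    """
    if min(n_accessions, genotypes_per_accession) <= 0:
        raise ValueError("accession and genotype counts must be positive")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    rng = rng or stream(config.seed, "landrace_collection")
    m = config.n_markers
    p = rng.uniform(0.1, 0.9, size=m)
    shape_a = p * (1.0 - fst) / fst
    shape_b = (1.0 - p) * (1.0 - fst) / fst

    dosage = np.empty((n_accessions * genotypes_per_accession, m))
    ids: list[str] = []
    accessions: list[str] = []
    for a in range(n_accessions):
        q = rng.beta(shape_a, shape_b)
        acc = f"Acc{a + 1:03d}"
        for g in range(genotypes_per_accession):
            row = a * genotypes_per_accession + g
            dosage[row] = 2.0 * (rng.random(m) < q)
            ids.append(f"{acc}_g{g + 1}")
            accessions.append(acc)
    chrom, pos = _marker_map(config)
    return GenotypeMatrix(
        genotype_ids=ids,
        marker_ids=[f"M{k + 1:05d}" for k in range(m)],
        dosage=dosage,
        chrom=chrom,
        pos=pos,
        accession_ids=accessions,
    )


def _marker_map(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spread markers over chromosomes (metadata only)."""
    m = config.n_markers
    chrom = np.array(
        [f"chr{(k % config.n_chromosomes) + 1:02d}" for k in range(m)]
    )
    pos = np.arange(1, m + 1) * 1000
    return chrom, pos


# ---------------------------------------------------------------------------
# trait architectures and phenotypes
# ---------------------------------------------------------------------------


def simulate_trait_architecture(
    config: SimulationConfig, trait: str, rng: np.random.Generator | None = None
) -> TraitArchitecture:
    """Sparse additive effects for one trait.

    ``qtl_count`` markers receive Normal(0, 1) effects.  For flowering time,
    ``major_gene_count`` of them are inflated so the major genes carry the
    bulk (>= 50%) of the genetic variance, reflecting the major-gene control
    of flowering in this crop.
    """
    qtl_count = config.qtl_for(trait)
    if qtl_count > config.n_markers:
        raise ValueError(
            f"qtl_count {qtl_count} exceeds n_markers {config.n_markers}"
        )
    rng = rng or stream(config.seed, f"architecture:{trait}")
    effects = np.zeros(config.n_markers)
    if qtl_count == 0:
        return TraitArchitecture(
            trait, effects, np.array([], dtype=int), np.array([], dtype=int)
        )
    qtl = np.sort(rng.choice(config.n_markers, size=qtl_count, replace=False))
    effects[qtl] = rng.normal(0.0, 1.0, size=qtl_count)

    majors = np.array([], dtype=int)
    n_major = config.major_gene_count if trait == "flowering_time" else 0
    n_major = min(n_major, qtl_count)
    if n_major > 0:
        majors = rng.choice(qtl, size=n_major, replace=False)
        minors = np.setdiff1d(qtl, majors)
        minor_ss = float(np.sum(effects[minors] ** 2)) if minors.size else 1.0
        # majors carry ~5x the summed minor variance -> dominant share
        magnitude = np.sqrt(5.0 * max(minor_ss, 1.0) / n_major)
        effects[majors] = magnitude * rng.choice([-1.0, 1.0], size=n_major)
    return TraitArchitecture(trait, effects, qtl, majors)


def correlated_architecture(
    base: TraitArchitecture,
    rho: float,
    config: SimulationConfig,
    label: str,
) -> TraitArchitecture:
    """An architecture genetically correlated ``rho`` with ``base``.

    Used to emulate a secondary evaluation site whose genotype responses are
    only modestly correlated with the primary site: effects are a
    ``rho``-weighted blend of the base effects and fresh independent effects
    of matched scale, at the same QTL positions.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = stream(config.seed, f"correlated:{label}")
    fresh = np.zeros_like(base.effects)
    if base.qtl_indices.size:
        scale = np.std(base.effects[base.qtl_indices])
        fresh[base.qtl_indices] = rng.normal(0.0, scale or 1.0, base.qtl_indices.size)
    effects = rho * base.effects + np.sqrt(1.0 - rho**2) * fresh
    return TraitArchitecture(
        trait=base.trait,
        effects=effects,
        qtl_indices=base.qtl_indices.copy(),
        major_indices=base.major_indices.copy(),
    )


def _scaled_genetic_values(
    geno: GenotypeMatrix, arch: TraitArchitecture, trait: str
) -> np.ndarray:
    """Genetic values rescaled to the trait's calibrated mean and SD."""
    mean, sd_g = TRAIT_BASELINES[trait]
    raw = arch.genetic_values(geno)
    sd_raw = raw.std()
    if sd_raw > 0:
        return mean + sd_g * (raw - raw.mean()) / sd_raw
    return np.full(geno.n_genotypes, mean)


def simulate_genotype_means(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Genotype-mean phenotypes at the trait's target heritability.

    Emulates the genotype means from a past phenotyping experiment (the GS
    training data): genetic value plus Normal noise with variance
    ``sd_g^2 (1 - h2) / h2``.
    """
    trait = arch.trait
    rng = rng or stream(config.seed, f"genotype_means:{trait}")
    gv = _scaled_genetic_values(geno, arch, trait)
    _, sd_g = TRAIT_BASELINES[trait]
    h2 = config.h2_for(trait)
    noise_sd = sd_g * np.sqrt((1.0 - h2) / h2)
    values = gv + rng.normal(0.0, noise_sd, size=len(gv))
    return pd.Series(values, index=geno.genotype_ids, name=trait)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    geno: GenotypeMatrix,
    architectures: dict[str, TraitArchitecture],
    config: SimulationConfig,
    traits: list[str] | None = None,
    sensitivity_overrides: dict[str, dict[str, np.ndarray]] | None = None,
    genetic_values: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> list[PlotObservation]:
    """Plot-level data for the 2 water x 2 soil factorial in RCB design.

    Each plot value decomposes as genotype genetic value + water + soil +
    water x soil + genotype-specific environmental sensitivities (GEI) +
    block-within-environment + plot error.  ``config.crossover_pairs``
    consecutive genotype pairs receive sign-flipped water sensitivities large
    enough that their grain-yield ranking reverses across water levels
    beyond the design's least significant difference.  Harvest index is
    derived per plot from grain and straw.

    ``sensitivity_overrides`` maps trait -> axis ('water', 'soil',
    'interaction') -> per-genotype array, replacing the randomly drawn
    sensitivities on that axis; this lets a caller make the environmental
    response genetic (e.g. soil response driven by lime-tolerance genetic
    values).  ``genetic_values`` (trait -> per-genotype array, trait units)
    overrides the architecture-derived values; use it when simulating a
    small subset of a population whose genetic scale must be preserved.
    """
    traits = traits or [t for t in TRAIT_BASELINES if t != "lime_susceptibility"]
    missing = [t for t in traits if t not in architectures]
    if missing:
        raise ValueError(f"no architecture provided for traits: {missing}")
    rng = rng or stream(config.seed, "trial")
    n = geno.n_genotypes
    r = config.n_blocks

    gv = {}
    for t in traits:
        if genetic_values is not None and t in genetic_values:
            arr = np.asarray(genetic_values[t], dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"genetic_values for {t} must have length {n}")
            gv[t] = arr.copy()
        else:
            gv[t] = _scaled_genetic_values(geno, architectures[t], t)
    sens: dict[str, dict[str, np.ndarray]] = {}
    for t in traits:
        _, sd_g = TRAIT_BASELINES[t]
        sens[t] = {
            "water": rng.normal(0.0, config.gei_sd_water * sd_g, n),
            "soil": rng.normal(0.0, config.gei_sd_soil * sd_g, n),
            "interaction": rng.normal(0.0, config.gei_sd_interaction * sd_g, n),
        }
    for t, axes in (sensitivity_overrides or {}).items():
        for axis, arr in axes.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"sensitivity override for {t}/{axis} must have length {n}"
                )
            sens[t][axis] = arr

    # implant crossover pairs on grain yield: equalize the pair's genetic
    # values and give them opposite water sensitivities with a margin that
    # clears the simulated LSD
    if "grain_yield" in traits and config.crossover_pairs > 0:
        if 2 * config.crossover_pairs > n:
            raise ValueError("not enough genotypes for the requested crossover pairs")
        _, sd_g = TRAIT_BASELINES["grain_yield"]
        sigma_p = config.plot_sd_for("grain_yield")
        lsd_est = 2.0 * sigma_p / np.sqrt(r)
        delta = max(1.25 * lsd_est, 0.5 * sd_g)
        for pair in range(config.crossover_pairs):
            i, j = 2 * pair, 2 * pair + 1
            base = 0.5 * (gv["grain_yield"][i] + gv["grain_yield"][j])
            gv["grain_yield"][i] = gv["grain_yield"][j] = base
            sens["grain_yield"]["water"][i] = delta
            sens["grain_yield"]["water"][j] = -delta

    block_effects = {
        t: rng.normal(
            0.0,
            config.block_sd * TRAIT_BASELINES[t][1],
            size=(len(WATER_LEVELS), len(SOIL_TYPES), r),
        )
        for t in traits
    }

    plots: list[PlotObservation] = []
    for wi, water in enumerate(WATER_LEVELS):
        xw = 1.0 if water == "drought" else -1.0
        for si, soil in enumerate(SOIL_TYPES):
            xs = 1.0 if soil == "sandy_loam" else -1.0
            for b in range(r):
                noise = {
                    t: rng.normal(0.0, config.plot_sd_for(t), n) for t in traits
                }
                for gi, gid in enumerate(geno.genotype_ids):
                    values: dict[str, float] = {}
                    for t in traits:
                        w_dev, s_dev, ws_dev = ENV_EFFECTS[t]
                        y = (
                            gv[t][gi]
                            + xw * w_dev
                            + xs * s_dev
                            + xw * xs * ws_dev
                            + xw * sens[t]["water"][gi]
                            + xs * sens[t]["soil"][gi]
                            + xw * xs * sens[t]["interaction"][gi]
                            + block_effects[t][wi, si, b]
                            + noise[t][gi]
                        )
                        if t in ("grain_yield", "straw_biomass"):
                            y = max(y, 0.0)
                        values[t] = float(y)
                    if "grain_yield" in values and "straw_biomass" in values:
                        total = values["grain_yield"] + values["straw_biomass"]
                        values["harvest_index"] = (
                            values["grain_yield"] / total if total > 0 else 0.0
                        )
                    plots.append(
                        PlotObservation(
                            genotype_id=gid,
                            water=water,
                            soil=soil,
                            block=b + 1,
                            traits=values,
                        )
                    )
    return plots


# ---------------------------------------------------------------------------
# GBS noise
# ---------------------------------------------------------------------------


def add_gbs_noise(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    bad_marker_ids: list[str] | None = None,
    bad_marker_rate_range: tuple[float, float] = (0.35, 0.55),
    bad_genotype_ids: list[str] | None = None,
    bad_genotype_rate_range: tuple[float, float] = (0.55, 0.75),
    high_het_marker_ids: list[str] | None = None,
    high_het_rate_range: tuple[float, float] = (0.35, 0.5),
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Inject GBS-style missingness and heterozygous miscalls.

    Baseline per-marker and per-genotype missing rates are drawn uniformly
    from the config ranges and combined per cell as independent dropout;
    homozygous calls flip to heterozygous at ``config.het_rate``.  Designated
    bad markers/genotypes/high-het markers receive rates from their own
    ranges, planting defects that exceed the standard QC thresholds so the
    filters are exercised.  With all rates zero and nothing designated the
    output equals the input.
    """
    for lo, hi in (bad_marker_rate_range, bad_genotype_rate_range, high_het_rate_range):
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("rate ranges must satisfy 0 <= lo <= hi < 1")
    rng = rng or stream(config.seed, "gbs_noise")
    n, m = geno.n_genotypes, geno.n_markers
    marker_index = {mid: j for j, mid in enumerate(geno.marker_ids)}
    genotype_index = {gid: i for i, gid in enumerate(geno.genotype_ids)}

    rm = rng.uniform(*config.missing_rate_marker_range, size=m)
    rg = rng.uniform(*config.missing_rate_genotype_range, size=n)
    if bad_marker_ids:
        idx = [marker_index[mid] for mid in bad_marker_ids]
        rm[idx] = rng.uniform(*bad_marker_rate_range, size=len(idx))
    if bad_genotype_ids:
        idx = [genotype_index[gid] for gid in bad_genotype_ids]
        rg[idx] = rng.uniform(*bad_genotype_rate_range, size=len(idx))

    het_prob = np.full(m, config.het_rate)
    if high_het_marker_ids:
        idx = [marker_index[mid] for mid in high_het_marker_ids]
        het_prob[idx] = rng.uniform(*high_het_rate_range, size=len(idx))

    out = geno.dosage.copy()
    # heterozygous miscalls on homozygous observed calls
    hom = (out == 0.0) | (out == 2.0)
    flips = hom & (rng.random((n, m)) < het_prob[None, :])
    out[flips] = 1.0
    # independent marker- and genotype-level dropout
    p_miss = 1.0 - (1.0 - rm[None, :]) * (1.0 - rg[:, None])
    drop = rng.random((n, m)) < p_miss
    out[drop] = np.nan

    result = geno.copy()
    result.dosage = out
    return result
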