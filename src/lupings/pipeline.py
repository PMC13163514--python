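"""End-to-end proof-of-concept runs on synthetic populations.

Three selection tracks mirror the validation programme:

* ``drought_lines`` — F6 breeding lines; rrBLUP and weighted-GBLUP grain
  yield predictions averaged, candidates restricted to a genomically
  predicted flowering window of m +/- s, predicted top/mid/bottom lines
  plus the phenotypically selected training-set top evaluated in a
  simulated 2 water x 2 soil factorial;
* ``drought_landraces`` — landrace genotypes; rrBLUP only, phenology
  constrained by observed accession-level flowering consistently within
  m +/- s in each of four evaluation environments;
* ``calcareous_lines`` — breeding lines; a standardized index of predicted
  calcareous-site yield and sign-inverted lime susceptibility, with
  secondary-site quartile constraints per selection role.

Every stage draws from a named sub-stream of the one global seed, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import GenotypeMatrix
from .prediction import (
    BreedingValueSet,
    cross_validate,
    fit_rrblup,
    fit_wgblup,
    predict_gebv,
)
from .qc import filter_matrix, impute_missing
from .selection import (
    SelectionRuleSet,
    average_predictions,
    lime_adaptation_index,
    multi_environment_window,
    phenology_window,
    quartile_mask,
    select_contrasting,
)
from .simulate import (
    SimulationConfig,
    TRAIT_BASELINES,
    _scaled_genetic_values,
    add_gbs_noise,
    correlated_architecture,
    simulate_factorial_cross_population,
    simulate_genotype_means,
    simulate_landrace_collection,
    simulate_trait_architecture,
    simulate_trial,
    stream,
)
from .trial import anova_partitioned, detect_crossover, lsd_value, plots_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic proof-of-concept run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    rules: SelectionRuleSet = field(default_factory=SelectionRuleSet)
    marker_miss_max: float = 0.3
    genotype_miss_max: float = 0.5
    het_max: float = 0.3
    impute_k: int = 10
    n_parents: int = 4
    lines_per_cross: int = 45
    inbreeding_generations: int = 5
    n_train_lines: int = 138
    n_train_landraces: int = 81
    n_train_lime: int = 140
    n_accessions: int = 113
    genotypes_per_accession: int = 4
    landrace_flowering_envs: int = 4
    accession_flowering_env_sd: float = 0.1  # x flowering genetic SD
    larissa_rho: float = 0.6   # genetic corr of calcareous-site and drought yield
    ens_rho: float = 0.4       # genetic corr of secondary and primary lime site
    soil_adapt_sd: float = 0.25  # genetic soil-sensitivity scale, x yield SD
    validation_plot_error_sd: float = 1.0  # x genetic SD; LSD ~0.45 t/ha
    cv_folds: int = 5
    cv_repeats: int = 3
    tracks: tuple[str, ...] = (
        "drought_lines",
        "drought_landraces",
        "calcareous_lines",
    )

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        rules = SelectionRuleSet(**raw.pop("rules", {}))
        return cls(sim=sim, rules=rules, **raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _qc(geno: GenotypeMatrix, config: PipelineConfig, label: str):
    noisy = add_gbs_noise(geno, config.sim, rng=stream(config.seed, f"noise:{label}"))
    filtered, report = filter_matrix(
        noisy,
        marker_miss_max=config.marker_miss_max,
        genotype_miss_max=config.genotype_miss_max,
        het_max=config.het_max,
    )
    return impute_missing(filtered, k_neighbors=config.impute_k), report


def _train_split(ids: list[str], n_train: int, seed: int, label: str):
    rng = stream(seed, f"split:{label}")
    perm = rng.permutation(len(ids))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def _phenotypic_top(
    yield_obs: pd.Series, flowering_obs: pd.Series, half_width_sd: float
) -> str:
    """Training-set top yielder whose observed flowering sits in m +/- s."""
    mask, _, _ = phenology_window(
        BreedingValueSet(flowering_obs, trait="flowering_time"), half_width_sd
    )
    pool = yield_obs[mask]
    if pool.empty:
        pool = yield_obs
    best = pool.max()
    return sorted(pool.index[pool == best])[0]


def _validation_lsd(sim: SimulationConfig) -> float:
    """Expected grain-yield LSD of the four-genotype validation factorial."""
    sigma_p = sim.plot_sd_for("grain_yield")
    r = sim.n_blocks
    df_resid = max(4 * 3 * (r - 1), 1)  # 4 environments, g=4 genotypes
    return lsd_value(sigma_p**2, df_resid, 2 * r)


def _crossover_water_sens(
    gv: np.ndarray, lsd_target: float, top_i: int = 0, mid_i: int = 1,
    bottom_i: int = 2,
) -> np.ndarray:
    """Water sensitivities implanting a top/mid crossover across treatments.

    The predicted top line gets a drought advantage and the mid line a
    moisture-favorable advantage, sized so the mid line overtakes the top
    under favorable water by about 1.6 LSD while staying above the bottom
    line under drought — the crossover pattern the validation trial is meant
    to expose.
    """
    sens = np.zeros(len(gv))
    gap_tm = gv[top_i] - gv[mid_i]
    gap_mb = gv[mid_i] - gv[bottom_i]
    d_fav = 1.6 * lsd_target
    mid_boost = max(0.4 * gap_mb, 0.0)
    top_boost = max(gap_tm + d_fav - mid_boost, 0.0)
    # do not let the favorable-water penalty drop the top line below bottom
    top_cap = max(gv[top_i] - gv[bottom_i] - 0.3 * lsd_target, 0.0)
    sens[top_i] = min(top_boost, top_cap)
    sens[mid_i] = -mid_boost
    return sens


def _validation_summary(
    plots, selected: dict[str, str], contrast_axis: str, stress_level: str
) -> dict:
    """ANOVA, per-condition genotype means, LSD, ordering and crossover."""
    table = anova_partitioned(plots, "grain_yield")
    df = plots_to_frame(plots)
    df = df[df["trait"] == "grain_yield"]
    cond_means = df.pivot_table(
        index="genotype", columns=contrast_axis, values="value", aggfunc="mean"
    )
    r = df["block"].nunique()
    n_per_mean = r * 2  # means taken across the other factorial axis
    lsd = lsd_value(
        table.loc["residual", "ms"], int(table.loc["residual", "df"]), n_per_mean
    )
    crossovers = detect_crossover(cond_means, lsd)
    stress_means = cond_means[stress_level]
    ordering = (
        stress_means[selected["top"]]
        > stress_means[selected["mid"]]
        > stress_means[selected["bottom"]]
    )
    top_vs_bottom = stress_means[selected["top"]] - stress_means[selected["bottom"]]
    return {
        "anova": table,
        "condition_means": cond_means,
        "lsd": lsd,
        "crossover_pairs_found": len(crossovers),
        "ordering_top_mid_bottom_under_stress": bool(ordering),
        "top_minus_bottom_under_stress": float(top_vs_bottom),
        "top_beats_bottom_significantly": bool(top_vs_bottom >= lsd),
        "stress_means": stress_means.to_dict(),
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the three selection tracks and return the run report.

    When ``outdir`` is given, intermediate artifacts (QC removal reports,
    fitted models, breeding values, selection decisions, ANOVA tables and
    the JSON/text report) are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    report: dict = {"seed": config.seed, "tracks": {}}
    need_lines = bool(
        {"drought_lines", "calcareous_lines"} & set(config.tracks)
    )
    need_landraces = "drought_landraces" in config.tracks

    # ---- shared populations and architectures ---------------------------
    arch = {
        t: simulate_trait_architecture(sim, t)
        for t in TRAIT_BASELINES
    }
    arch_larissa = correlated_architecture(
        arch["grain_yield"], config.larissa_rho, sim, "larissa_yield"
    )
    arch_ens = correlated_architecture(arch_larissa, config.ens_rho, sim, "ens_yield")

    trial_traits = [t for t in TRAIT_BASELINES if t != "lime_susceptibility"]

    def population_gv(pop: GenotypeMatrix, arch_map: dict) -> dict[str, np.ndarray]:
        return {
            t: _scaled_genetic_values(pop, arch_map[t], t) for t in trial_traits
        }

    def subset_gv(
        pop_gv: dict[str, np.ndarray], pop: GenotypeMatrix, ids: list[str]
    ) -> dict[str, np.ndarray]:
        index = {g: i for i, g in enumerate(pop.genotype_ids)}
        rows = np.array([index[g] for g in ids])
        return {t: v[rows] for t, v in pop_gv.items()}

    if need_lines:
        lines = simulate_factorial_cross_population(
            sim,
            n_parents_a=config.n_parents,
            n_parents_b=config.n_parents,
            lines_per_cross=config.lines_per_cross,
            inbreeding_generations=config.inbreeding_generations,
        )
        lines_gv = population_gv(lines, arch)
        lines_qc, lines_removal = _qc(lines, config, "lines")
        if out is not None:
            lines_removal.to_csv(out / "qc_removals_lines.csv", index=False)

        # track A training data and flowering model (the flowering model is
        # shared with the calcareous-soil track)
        train_ids, indep_ids = _train_split(
            lines_qc.genotype_ids, config.n_train_lines, config.seed, "lines_drought"
        )
        train = lines_qc.subset(genotypes=np.array(train_ids))
        indep = lines_qc.subset(genotypes=np.array(indep_ids))

        # phenotypes arise from the true genomes, not the QC'd marker panel
        y_train = simulate_genotype_means(
            lines.subset(genotypes=np.array(train_ids)), arch["grain_yield"], sim,
            rng=stream(config.seed, "pheno:lines_drought_yield"),
        )
        ft_train = simulate_genotype_means(
            lines.subset(genotypes=np.array(train_ids)), arch["flowering_time"], sim,
            rng=stream(config.seed, "pheno:lines_flowering"),
        )
        ft_model = fit_wgblup(train, ft_train, trait="flowering_time")

    if need_landraces:
        landraces = simulate_landrace_collection(
            sim,
            n_accessions=config.n_accessions,
            genotypes_per_accession=config.genotypes_per_accession,
        )
        landraces_gv = population_gv(landraces, arch)
        landraces_qc, landraces_removal = _qc(landraces, config, "landraces")
        if out is not None:
            landraces_removal.to_csv(out / "qc_removals_landraces.csv", index=False)

    # ---- track A: breeding lines, adaptation to drought ------------------
    if "drought_lines" in config.tracks:
        rr = fit_rrblup(train, y_train, trait="grain_yield")
        wg = fit_wgblup(train, y_train, weight_source=rr, trait="grain_yield")
        yield_pred = average_predictions(
            [predict_gebv(rr, indep), predict_gebv(wg, indep)]
        )
        ft_pred = predict_gebv(ft_model, indep)
        window_mask, ft_m, ft_s = phenology_window(
            ft_pred, config.rules.half_width_sd
        )
        decision = select_contrasting(yield_pred, window_mask)
        ps_top = _phenotypic_top(y_train, ft_train, config.rules.half_width_sd)

        cv = cross_validate(
            train, y_train, k=config.cv_folds, repeats=config.cv_repeats,
            seed=config.seed,
        )

        selected = {
            "top": decision.top, "mid": decision.mid, "bottom": decision.bottom
        }
        val_ids = [decision.top, decision.mid, decision.bottom, ps_top]
        val_geno = lines.subset(genotypes=np.array(val_ids))
        val_sim = dataclasses.replace(
            sim, crossover_pairs=0, plot_error_sd=config.validation_plot_error_sd
        )
        val_gv = subset_gv(lines_gv, lines, val_ids)
        val_plots = simulate_trial(
            val_geno,
            arch,
            val_sim,
            sensitivity_overrides={
                "grain_yield": {
                    "water": _crossover_water_sens(
                        val_gv["grain_yield"], _validation_lsd(val_sim)
                    )
                }
            },
            genetic_values=val_gv,
            rng=stream(config.seed, "trial:lines_drought"),
        )
        summary = _validation_summary(val_plots, selected, "water", "drought")
        report["tracks"]["drought_lines"] = {
            "n_training": len(train_ids),
            "n_independent": len(indep_ids),
            "n_candidates_after_window": int(window_mask.sum()),
            "window_pass_pct": round(100.0 * window_mask.mean(), 1),
            "flowering_window": {"m": round(ft_m, 3), "s": round(ft_s, 3)},
            "selected": selected,
            "phenotypic_top": ps_top,
            "cv_predictive_ability": round(cv.mean_r, 3),
            **{
                k: v
                for k, v in summary.items()
                if k not in ("anova", "condition_means")
            },
        }
        if out is not None:
            rr.to_json(out / "model_lines_rrblup.json")
            wg.to_json(out / "model_lines_wgblup.json")
            yield_pred.to_csv(out / "gebv_lines_yield.csv")
            ft_pred.to_csv(out / "gebv_lines_flowering.csv")
            summary["anova"].to_csv(out / "anova_drought_lines.csv")
            summary["condition_means"].to_csv(out / "means_drought_lines.csv")

    # ---- track B: landrace genotypes, adaptation to drought ---------------
    if need_landraces:
        _run_landrace_track(config, sim, arch, landraces, landraces_gv,
                            landraces_qc, subset_gv, report, out)

    # ---- track C: breeding lines, adaptation to calcareous soil ----------
    if "calcareous_lines" in config.tracks:
        _run_lime_track(config, sim, arch, arch_larissa, arch_ens, lines,
                        lines_qc, ft_model, population_gv, subset_gv, report, out)

    report["all_tracks_ordered_under_stress"] = all(
        report["tracks"][t]["ordering_top_mid_bottom_under_stress"]
        for t in report["tracks"]
    )
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "report.txt", "w") as fh:
            fh.write(_format_report(report))
    return report


def _run_landrace_track(
    config, sim, arch, landraces, landraces_gv, landraces_qc, subset_gv,
    report, out
) -> None:
    """Landrace genotypes selected for adaptation to drought."""
    lg_train_ids, lg_indep_ids = _train_split(
        landraces_qc.genotype_ids,
        config.n_train_landraces,
        config.seed,
        "landraces_drought",
    )
    lg_train = landraces_qc.subset(genotypes=np.array(lg_train_ids))
    lg_indep = landraces_qc.subset(genotypes=np.array(lg_indep_ids))
    lg_y_train = simulate_genotype_means(
        landraces.subset(genotypes=np.array(lg_train_ids)), arch["grain_yield"], sim,
        rng=stream(config.seed, "pheno:landrace_yield"),
    )
    lg_rr = fit_rrblup(lg_train, lg_y_train, trait="grain_yield")
    lg_pred = predict_gebv(lg_rr, lg_indep)

    # observed accession-level flowering in each evaluation environment
    acc_of = dict(zip(landraces.genotype_ids, landraces.accession_ids))
    ft_gv = pd.Series(
        _scaled_genetic_values(landraces, arch["flowering_time"], "flowering_time"),
        index=landraces.genotype_ids,
    )
    acc_gv = ft_gv.groupby(acc_of).mean()
    _, ft_sd = TRAIT_BASELINES["flowering_time"]
    env_rng = stream(config.seed, "landrace_flowering_envs")
    ft_by_env = {
        f"env{k + 1}": BreedingValueSet(
            acc_gv
            + env_rng.normal(
                0.0, config.accession_flowering_env_sd * ft_sd, len(acc_gv)
            ),
            trait="flowering_time",
        )
        for k in range(config.landrace_flowering_envs)
    }
    acc_mask = multi_environment_window(ft_by_env, config.rules.half_width_sd)
    geno_mask = pd.Series(
        [acc_mask.get(acc_of[g], False) for g in lg_pred.values.index],
        index=lg_pred.values.index,
    )
    lg_decision = select_contrasting(lg_pred, geno_mask)
    lg_ps_candidates = lg_y_train[
        [acc_mask.get(acc_of[g], False) for g in lg_y_train.index]
    ]
    if lg_ps_candidates.empty:
        lg_ps_candidates = lg_y_train
    lg_ps_top = sorted(
        lg_ps_candidates.index[lg_ps_candidates == lg_ps_candidates.max()]
    )[0]

    lg_selected = {
        "top": lg_decision.top, "mid": lg_decision.mid, "bottom": lg_decision.bottom
    }
    lg_val_ids = [lg_decision.top, lg_decision.mid, lg_decision.bottom, lg_ps_top]
    lg_val = landraces.subset(genotypes=np.array(lg_val_ids))
    lg_val_sim = dataclasses.replace(
        sim, crossover_pairs=0, plot_error_sd=config.validation_plot_error_sd
    )
    lg_val_gv = subset_gv(landraces_gv, landraces, lg_val_ids)
    lg_val_plots = simulate_trial(
        lg_val,
        arch,
        lg_val_sim,
        sensitivity_overrides={
            "grain_yield": {
                "water": _crossover_water_sens(
                    lg_val_gv["grain_yield"], _validation_lsd(lg_val_sim)
                )
            }
        },
        genetic_values=lg_val_gv,
        rng=stream(config.seed, "trial:landraces_drought"),
    )
    lg_summary = _validation_summary(lg_val_plots, lg_selected, "water", "drought")
    report["tracks"]["drought_landraces"] = {
        "n_training": len(lg_train_ids),
        "n_independent": len(lg_indep_ids),
        "n_accessions_pass_window": int(acc_mask.sum()),
        "accession_window_pass_pct": round(
            100.0 * acc_mask.sum() / len(acc_mask), 1
        ),
        "n_candidates_after_window": int(geno_mask.sum()),
        "selected": lg_selected,
        "phenotypic_top": lg_ps_top,
        **{
            k: v
            for k, v in lg_summary.items()
            if k not in ("anova", "condition_means")
        },
    }
    if out is not None:
        lg_rr.to_json(out / "model_landraces_rrblup.json")
        lg_pred.to_csv(out / "gebv_landraces_yield.csv")
        lg_summary["anova"].to_csv(out / "anova_drought_landraces.csv")
        lg_summary["condition_means"].to_csv(out / "means_drought_landraces.csv")


def _run_lime_track(
    config, sim, arch, arch_larissa, arch_ens, lines, lines_qc, ft_model,
    population_gv, subset_gv, report, out
) -> None:
    """Breeding lines selected for adaptation to moderately calcareous soil."""
    lime_train_ids, lime_indep_ids = _train_split(
        lines_qc.genotype_ids, config.n_train_lime, config.seed, "lines_lime"
    )
    lime_train = lines_qc.subset(genotypes=np.array(lime_train_ids))
    lime_indep = lines_qc.subset(genotypes=np.array(lime_indep_ids))

    lime_train_raw = lines.subset(genotypes=np.array(lime_train_ids))
    y_larissa = simulate_genotype_means(
        lime_train_raw, arch_larissa, sim,
        rng=stream(config.seed, "pheno:larissa_yield"),
    )
    y_susc = simulate_genotype_means(
        lime_train_raw, arch["lime_susceptibility"], sim,
        rng=stream(config.seed, "pheno:lime_susceptibility"),
    )
    y_ens = simulate_genotype_means(
        lime_train_raw, arch_ens, sim, rng=stream(config.seed, "pheno:ens_yield")
    )
    m_larissa = fit_rrblup(lime_train, y_larissa, trait="grain_yield")
    m_susc = fit_rrblup(lime_train, y_susc, trait="lime_susceptibility")
    m_ens = fit_rrblup(lime_train, y_ens, trait="grain_yield")

    lime_index = lime_adaptation_index(
        predict_gebv(m_larissa, lime_indep), predict_gebv(m_susc, lime_indep)
    )
    ens_pred = predict_gebv(m_ens, lime_indep)
    lime_ft_pred = predict_gebv(ft_model, lime_indep)
    lime_window, _, _ = phenology_window(lime_ft_pred, config.rules.half_width_sd)
    secondary = {
        role: quartile_mask(ens_pred, rule)
        for role, rule in config.rules.secondary_rules.items()
    }
    lime_decision = select_contrasting(lime_index, lime_window, secondary)
    lime_ft_train = simulate_genotype_means(
        lime_train_raw, arch["flowering_time"], sim,
        rng=stream(config.seed, "pheno:lime_flowering"),
    )
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    lime_ps_top = _phenotypic_top(
        z(y_larissa) + z(y_ens), lime_ft_train, config.rules.half_width_sd
    )

    lime_selected = {
        "top": lime_decision.top,
        "mid": lime_decision.mid,
        "bottom": lime_decision.bottom,
    }
    lime_val_ids = [
        lime_decision.top, lime_decision.mid, lime_decision.bottom, lime_ps_top
    ]
    lime_val = lines.subset(genotypes=np.array(lime_val_ids))
    # soil response driven by genetic lime tolerance: tolerant genotypes
    # lose less in the calcareous (silty-clay) environment; tolerance is
    # standardized on the population scale before subsetting
    susc_pop = arch["lime_susceptibility"].genetic_values(lines)
    sd_susc = susc_pop.std()
    z_tol_pop = (
        -(susc_pop - susc_pop.mean()) / sd_susc
        if sd_susc > 0
        else np.zeros(lines.n_genotypes)
    )
    line_index = {g: i for i, g in enumerate(lines.genotype_ids)}
    z_tol = z_tol_pop[[line_index[g] for g in lime_val_ids]]
    _, yield_sd = TRAIT_BASELINES["grain_yield"]
    overrides = {
        "grain_yield": {"soil": -config.soil_adapt_sd * yield_sd * z_tol}
    }
    lime_arch = {**arch, "grain_yield": arch_larissa}
    lime_pop_gv = population_gv(lines, lime_arch)
    lime_val_gv = subset_gv(lime_pop_gv, lines, lime_val_ids)
    lime_val_plots = simulate_trial(
        lime_val,
        lime_arch,
        dataclasses.replace(
            sim, crossover_pairs=0, plot_error_sd=config.validation_plot_error_sd
        ),
        sensitivity_overrides=overrides,
        genetic_values=lime_val_gv,
        rng=stream(config.seed, "trial:lines_lime"),
    )
    lime_summary = _validation_summary(
        lime_val_plots, lime_selected, "soil", "silty_clay"
    )
    report["tracks"]["calcareous_lines"] = {
        "n_training": len(lime_train_ids),
        "n_independent": len(lime_indep_ids),
        "n_candidates_after_window": int(lime_window.sum()),
        "selected": lime_selected,
        "phenotypic_top": lime_ps_top,
        **{
            k: v
            for k, v in lime_summary.items()
            if k not in ("anova", "condition_means")
        },
    }
    if out is not None:
        m_larissa.to_json(out / "model_lime_primary_rrblup.json")
        m_ens.to_json(out / "model_lime_secondary_rrblup.json")
        lime_index.to_csv(out / "gebv_lime_index.csv")
        lime_summary["anova"].to_csv(out / "anova_calcareous_lines.csv")
        lime_summary["condition_means"].to_csv(out / "means_calcareous_lines.csv")


def _format_report(report: dict) -> str:
    lines = [f"proof-of-concept run, seed {report['seed']}", ""]
    for track, info in report["tracks"].items():
        lines.append(f"[{track}]")
        for key, value in info.items():
            lines.append(f"  {key}: {value}")
        lines.append("")
    lines.append(
        "all tracks realized top > mid > bottom under stress: "
        f"{report['all_tracks_ordered_under_stress']}"
    )
    return "\n".join(lines) + "\n"
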