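"""Phenology-constrained selection of contrasting genotypes.

The selection protocol this module implements picks predicted top-, mid- and
bottom-yielding genotypes for a proof-of-concept comparison, under two kinds
of constraint:

* a phenology window — only genotypes whose (predicted or observed) onset of
  flowering lies within one standard deviation of the population mean
  (``m +/- s``) are candidates, so that selection exploits drought
  *resistance* rather than drought *escape* by extreme earliness; for
  landrace material the window must hold consistently in every evaluation
  environment;
* optional secondary-site constraints — e.g. a top candidate must also sit
  in the top quartile of predicted yield at a secondary site, the bottom
  candidate below its average, the mid candidate in the middle quartiles.

For adaptation to calcareous soil, yield and a lime-susceptibility score are
combined into a single index: both are standardized to zero mean and unit SD,
susceptibility is sign-inverted into tolerance, and the two z-scores are
averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction import BreedingValueSet

__all__ = [
    "SelectionRuleSet",
    "SelectionDecision",
    "phenology_window",
    "multi_environment_window",
    "average_predictions",
    "lime_adaptation_index",
    "quartile_mask",
    "select_contrasting",
]

QUARTILE_RULES = ("top_quartile", "below_average", "middle_quartiles")


@dataclass
class SelectionRuleSet:
    """Tunable knobs of the selection protocol.

    ``half_width_sd`` is the phenology-window half-width in SD units;
    ``secondary_rules`` maps each role (top/mid/bottom) to a quartile rule
    applied to a secondary-site prediction.
    """

    half_width_sd: float = 1.0
    secondary_rules: dict[str, str] = field(
        default_factory=lambda: {
            "top": "top_quartile",
            "mid": "middle_quartiles",
            "bottom": "below_average",
        }
    )
    tie_policy: str = "lexicographic_id"

    def __post_init__(self) -> None:
        if not self.half_width_sd > 0:
            raise ValueError("half_width_sd must be positive")
        for role, rule in self.secondary_rules.items():
            if rule not in QUARTILE_RULES:
                raise ValueError(f"unknown quartile rule {rule!r} for role {role!r}")


@dataclass
class SelectionDecision:
    """Outcome of a top/mid/bottom contrast selection."""

    top: str
    mid: str
    bottom: str
    candidate_ids: list[str]
    index_values: pd.Series
    mid_tie: bool = False

    def __post_init__(self) -> None:
        chosen = {self.top, self.mid, self.bottom}
        if len(chosen) != 3:
            raise ValueError("top, mid and bottom must be three distinct genotypes")
        if not chosen <= set(self.candidate_ids):
            raise ValueError("selected genotypes must be candidates")


def phenology_window(
    ft: BreedingValueSet, half_width_sd: float = 1.0
) -> tuple[pd.Series, float, float]:
    """Mask of genotypes whose flowering lies within ``m +/- half_width_sd*s``.

    ``m`` and ``s`` are the mean and sample SD of the flowering values over
    all genotypes; window bounds are inclusive.  Returns (mask, m, s).
    On Normal flowering data the expected pass fraction at the default
    one-SD window is 2*Phi(1) - 1, about 68%.
    """
    if len(ft.values) < 2:
        raise ValueError("phenology window needs at least 2 genotypes")
    if not half_width_sd > 0:
        raise ValueError("half_width_sd must be positive")
    m, s = ft.m, ft.s
    mask = (ft.values - m).abs() <= half_width_sd * s
    return mask, m, s


def multi_environment_window(
    ft_by_env: dict[str, BreedingValueSet], half_width_sd: float = 1.0
) -> pd.Series:
    """Conjunction of per-environment phenology windows.

    A genotype passes iff it lies within ``m +/- s`` (computed separately per
    environment) in EVERY environment.  Genotypes absent from any environment
    are excluded with a warning.
    """
    if not ft_by_env:
        raise ValueError("need at least one environment")
    masks = {}
    for env, bv in ft_by_env.items():
        masks[env], _, _ = phenology_window(bv, half_width_sd)
    all_ids = sorted(set().union(*(m.index for m in masks.values())))
    common = set(all_ids)
    for m in masks.values():
        common &= set(m.index)
    dropped = [g for g in all_ids if g not in common]
    if dropped:
        warnings.warn(
            f"{len(dropped)} genotype(s) absent from some environment were excluded",
            stacklevel=2,
        )
    out = pd.Series(False, index=pd.Index(all_ids))
    for gid in common:
        out[gid] = all(masks[env][gid] for env in masks)
    return out


def average_predictions(bv_sets: list[BreedingValueSet]) -> BreedingValueSet:
    """Per-genotype arithmetic mean across model predictions.

    Used to combine rrBLUP and WGBLUP breeding values into a single ranking.
    """
    if not bv_sets:
        raise ValueError("need at least one breeding-value set")
    first = bv_sets[0]
    ids = set(first.values.index)
    for bv in bv_sets[1:]:
        if set(bv.values.index) != ids:
            raise ValueError("breeding-value sets cover different genotypes")
        if bv.trait != first.trait:
            raise ValueError("breeding-value sets are for different traits")
    stacked = pd.concat([bv.values for bv in bv_sets], axis=1)
    return BreedingValueSet(values=stacked.mean(axis=1), trait=first.trait)


def lime_adaptation_index(
    yield_bv: BreedingValueSet, susceptibility_bv: BreedingValueSet
) -> BreedingValueSet:
    """Combined adaptation-to-calcareous-soil index.

    Both inputs are standardized to zero mean and unit SD; the susceptibility
    z-score is sign-inverted into a tolerance score; the index is the mean of
    the yield and tolerance z-scores.  The index has mean zero by
    construction.
    """
    if set(yield_bv.values.index) != set(susceptibility_bv.values.index):
        raise ValueError("yield and susceptibility sets cover different genotypes")
    if yield_bv.s == 0 or susceptibility_bv.s == 0:
        raise ValueError("cannot standardize a zero-variance trait")
    z_yield = (yield_bv.values - yield_bv.m) / yield_bv.s
    z_susc = (susceptibility_bv.values - susceptibility_bv.m) / susceptibility_bv.s
    z_susc = z_susc.loc[z_yield.index]
    index = (z_yield - z_susc) / 2.0
    return BreedingValueSet(values=index, trait="lime_adaptation")


def quartile_mask(secondary_bv: BreedingValueSet, rule: str) -> pd.Series:
    """Secondary-site constraint mask.

    Percentiles use linear interpolation between order statistics;
    ``top_quartile`` keeps values >= the 75th percentile, ``below_average``
    keeps values strictly below the mean, ``middle_quartiles`` keeps
    25th percentile <= value < 75th percentile.
    """
    if len(secondary_bv.values) < 4:
        raise ValueError("quartile rules need at least 4 genotypes")
    v = secondary_bv.values
    if rule == "top_quartile":
        return v >= np.percentile(v, 75)
    if rule == "below_average":
        return v < v.mean()
    if rule == "middle_quartiles":
        return (v >= np.percentile(v, 25)) & (v < np.percentile(v, 75))
    raise ValueError(f"unknown quartile rule {rule!r}; choose one of {QUARTILE_RULES}")


def select_contrasting(
    primary_bv: BreedingValueSet,
    candidate_mask: pd.Series | None = None,
    secondary_masks: dict[str, pd.Series] | None = None,
    mid_reference: str = "candidates",
) -> SelectionDecision:
    """Pick the predicted top-, mid- and bottom-performing genotypes.

    ``candidate_mask`` (typically a phenology window) restricts the pool;
    ``secondary_masks`` optionally adds per-role constraints (keys among
    top/mid/bottom).  ``top`` is the maximum primary value among top-role
    candidates, ``bottom`` the minimum among bottom-role candidates, and
    ``mid`` the candidate closest to the mean of the candidate values
    (``mid_reference='all'`` measures closeness to the pre-filter mean
    instead).  Ties break to the lexicographically smallest genotype id.
    """
    values = primary_bv.values
    if candidate_mask is None:
        candidate_mask = pd.Series(True, index=values.index)
    candidate_mask = candidate_mask.reindex(values.index, fill_value=False)
    candidates = values[candidate_mask]
    if len(candidates) < 3:
        raise ValueError(
            f"only {len(candidates)} candidates after masking; need at least 3"
        )
    secondary_masks = secondary_masks or {}

    def role_pool(role: str) -> pd.Series:
        pool = candidates
        if role in secondary_masks:
            mask = secondary_masks[role].reindex(pool.index, fill_value=False)
            pool = pool[mask]
        if pool.empty:
            raise ValueError(
                f"no candidate satisfies the {role!r}-role constraints "
                f"(binding constraint: secondary mask)"
            )
        return pool

    def argbest(pool: pd.Series, score: pd.Series) -> tuple[str, bool]:
        best = score.min()
        winners = sorted(score.index[score == best])
        return winners[0], len(winners) > 1

    top_pool = role_pool("top")
    bottom_pool = role_pool("bottom")
    mid_pool = role_pool("mid")
    if mid_reference == "candidates":
        mid_center = candidates.mean()
    elif mid_reference == "all":
        mid_center = values.mean()
    else:
        raise ValueError("mid_reference must be 'candidates' or 'all'")

    top, _ = argbest(top_pool, -top_pool)
    bottom, _ = argbest(bottom_pool, bottom_pool)
    mid_scores = (mid_pool - mid_center).abs()
    # top/bottom must stay distinct from mid
    mid_scores = mid_scores.drop(index=[g for g in (top, bottom) if g in mid_scores])
    if mid_scores.empty:
        raise ValueError("no candidate left for the 'mid' role after exclusions")
    mid, mid_tie = argbest(mid_scores, mid_scores)
    return SelectionDecision(
        top=top,
        mid=mid,
        bottom=bottom,
        candidate_ids=list(candidates.index),
        index_values=candidates,
        mid_tie=mid_tie,
    )
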