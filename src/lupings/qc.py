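"""SNP-matrix quality control: marker statistics, filtering, imputation.

GBS dosage matrices arrive with substantial missingness and a tail of
unreliable markers (excess heterozygosity from paralog collapse, high missing
rate from low coverage).  The standard cleanup is: drop monomorphic markers,
drop markers with missing rate >= 0.3 or heterozygosity >= 0.3, drop
genotypes with missing rate >= 0.5, then impute the remaining gaps to obtain
the complete matrix that genomic prediction requires.

Marker-level filters are applied before the genotype-level filter, and
genotype missing rates are recomputed on the marker-filtered matrix; the
threshold semantics are strict (a marker is kept iff its statistic is
strictly below the threshold).  Imputation is a deterministic
k-nearest-genotype mode imputer: for each missing call, the mode of the
calls of the k genotypes most similar to the target (by shared non-missing
identity) at that marker, falling back to the marker mode when no informative
neighbour exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = ["MarkerStats", "compute_stats", "filter_matrix", "impute_missing"]


@dataclass
class MarkerStats:
    """Per-marker and per-genotype QC statistics.

    All marker series are indexed by marker id; ``genotype_missing_rate`` by
    genotype id.  Heterozygosity is the fraction of non-missing calls equal
    to 1; a marker with zero non-missing calls has heterozygosity 0 by
    convention and is flagged monomorphic.
    """

    marker_missing_rate: pd.Series
    marker_heterozygosity: pd.Series
    maf: pd.Series
    monomorphic: pd.Series
    genotype_missing_rate: pd.Series


def compute_stats(geno: GenotypeMatrix) -> MarkerStats:
    """Compute the QC statistics the dosage-matrix filters act on."""
    if geno.n_genotypes == 0 or geno.n_markers == 0:
        raise ValueError("genotype matrix is empty")
    d = geno.dosage
    obs = ~np.isnan(d)
    n_obs_marker = obs.sum(axis=0)

    marker_missing = 1.0 - n_obs_marker / geno.n_genotypes
    genotype_missing = 1.0 - obs.sum(axis=1) / geno.n_markers

    with np.errstate(invalid="ignore"):
        het = np.where(
            n_obs_marker > 0,
            np.nansum(d == 1, axis=0) / np.maximum(n_obs_marker, 1),
            0.0,
        )
        freq = np.where(
            n_obs_marker > 0,
            np.nansum(d, axis=0) / np.maximum(2 * n_obs_marker, 1),
            0.0,
        )
    maf = np.minimum(freq, 1.0 - freq)
    monomorphic = maf == 0.0

    mi = pd.Index(geno.marker_ids, name="marker")
    gi = pd.Index(geno.genotype_ids, name="genotype")
    return MarkerStats(
        marker_missing_rate=pd.Series(marker_missing, index=mi),
        marker_heterozygosity=pd.Series(het, index=mi),
        maf=pd.Series(maf, index=mi),
        monomorphic=pd.Series(monomorphic, index=mi),
        genotype_missing_rate=pd.Series(genotype_missing, index=gi),
    )


def filter_matrix(
    geno: GenotypeMatrix,
    stats: MarkerStats | None = None,
    marker_miss_max: float = 0.3,
    genotype_miss_max: float = 0.5,
    het_max: float = 0.3,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the standard GBS dosage-matrix filters.

    Markers are kept iff not monomorphic, missing rate < ``marker_miss_max``
    and heterozygosity < ``het_max``; genotypes are then kept iff their
    missing rate, recomputed over the retained markers, is
    < ``genotype_miss_max``.

    Returns the filtered matrix and a removal report with one row per
    removed item (columns: item, type, reason, value).  Each removed item
    carries a single reason, chosen in the priority order monomorphic,
    missing rate, heterozygosity.
    """
    for name, thr in (
        ("marker_miss_max", marker_miss_max),
        ("genotype_miss_max", genotype_miss_max),
        ("het_max", het_max),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    if stats is None:
        stats = compute_stats(geno)

    report_rows: list[tuple[str, str, str, float]] = []
    keep_marker = np.ones(geno.n_markers, dtype=bool)
    for j, mid in enumerate(geno.marker_ids):
        if drop_monomorphic and stats.monomorphic.iloc[j]:
            keep_marker[j] = False
            report_rows.append((mid, "marker", "monomorphic", stats.maf.iloc[j]))
        elif stats.marker_missing_rate.iloc[j] >= marker_miss_max:
            keep_marker[j] = False
            report_rows.append(
                (mid, "marker", "missing_rate", stats.marker_missing_rate.iloc[j])
            )
        elif stats.marker_heterozygosity.iloc[j] >= het_max:
            keep_marker[j] = False
            report_rows.append(
                (mid, "marker", "heterozygosity", stats.marker_heterozygosity.iloc[j])
            )

    trimmed = geno.subset(markers=keep_marker)
    keep_genotype = np.ones(trimmed.n_genotypes, dtype=bool)
    if trimmed.n_markers > 0:
        geno_missing = np.isnan(trimmed.dosage).mean(axis=1)
    else:
        geno_missing = np.zeros(trimmed.n_genotypes)
    for i, gid in enumerate(trimmed.genotype_ids):
        if geno_missing[i] >= genotype_miss_max:
            keep_genotype[i] = False
            report_rows.append((gid, "genotype", "missing_rate", geno_missing[i]))

    filtered = trimmed.subset(genotypes=keep_genotype)
    report = pd.DataFrame(report_rows, columns=["item", "type", "reason", "value"])
    return filtered, report


def _pairwise_identity(dosage: np.ndarray) -> np.ndarray:
    """Fraction of shared non-missing calls that are identical, per pair."""
    obs = (~np.isnan(dosage)).astype(float)
    shared = obs @ obs.T
    equal = np.zeros_like(shared)
    for value in (0.0, 1.0, 2.0):
        ind = (dosage == value).astype(float)
        equal += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared > 0, equal / shared, 0.0)
    return sim


def impute_missing(geno: GenotypeMatrix, k_neighbors: int = 10) -> GenotypeMatrix:
    """Fill missing calls by the mode of the k most similar genotypes.

    Similarity between genotypes is the fraction of identical calls over
    their shared non-missing markers.  For each missing call the mode of the
    neighbours' calls at that marker is used (neighbour order: similarity
    descending, then input order; mode ties resolve to the lowest dosage).
    Falls back to the marker mode when no neighbour carries a call.
    Observed calls are never altered.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be positive")
    d = geno.dosage
    missing = np.isnan(d)
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        bad = [geno.marker_ids[j] for j in np.flatnonzero(fully_missing)[:5]]
        raise ValueError(f"markers with no observed calls cannot be imputed: {bad}")
    if not missing.any():
        return geno.copy()

    sim = _pairwise_identity(d)
    np.fill_diagonal(sim, -1.0)  # a genotype is not its own neighbour
    out = d.copy()
    for j in np.flatnonzero(missing.any(axis=0)):
        observed_rows = np.flatnonzero(~missing[:, j])
        calls = d[observed_rows, j]
        # marker mode (lowest dosage on ties) as the fallback
        vals, counts = np.unique(calls, return_counts=True)
        marker_mode = vals[np.argmax(counts)]
        for i in np.flatnonzero(missing[:, j]):
            cand = observed_rows
            if cand.size == 0:
                out[i, j] = marker_mode
                continue
            order = np.lexsort((cand, -sim[i, cand]))
            top = cand[order[:k_neighbors]]
            neigh_calls = d[top, j]
            vals, counts = np.unique(neigh_calls, return_counts=True)
            out[i, j] = vals[np.argmax(counts)]
    assert not np.isnan(out).any()
    result = geno.copy()
    result.dosage = out
    return result
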