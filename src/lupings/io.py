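"""Reading and writing the pipeline's file formats.

Genotypes travel as delimited dosage matrices, minimal GT-only VCF, or a
HapMap-like table; phenotypes as a tidy plot CSV with columns genotype,
water, soil, block, trait, value.
"""

from __future__ import annotations

import os

import pandas as pd

from .matrix import GenotypeMatrix
from .trial import PlotObservation, SOIL_TYPES, WATER_LEVELS, frame_to_plots, plots_to_frame

__all__ = ["load_genotypes", "save_genotypes", "load_phenotypes", "save_phenotypes"]

_FORMATS = ("matrix", "vcf", "hapmap")


def load_genotypes(path, format: str = "matrix") -> GenotypeMatrix:
    """Load a dosage matrix; unknown calls become missing.

    ``format`` is one of ``matrix`` (delimited genotypes x markers table),
    ``vcf`` (diploid GT fields) or ``hapmap`` (marker rows with two-letter
    calls).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty input file: {path}")
    if format == "matrix":
        return GenotypeMatrix.read_matrix(path)
    if format == "vcf":
        return GenotypeMatrix.read_vcf(path)
    if format == "hapmap":
        return GenotypeMatrix.read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}; choose one of {_FORMATS}")


def save_genotypes(geno: GenotypeMatrix, path, format: str = "matrix") -> None:
    if format == "matrix":
        geno.write_matrix(path)
    elif format == "vcf":
        geno.write_vcf(path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


def load_phenotypes(path) -> list[PlotObservation]:
    """Load tidy plot records, validating factor levels.

    Water levels must be in {drought, favorable} and soil types in
    {sandy_loam, silty_clay}; the offending row number is reported otherwise.
    """
    df = pd.read_csv(path)
    required = {"genotype", "water", "soil", "block", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    bad_water = ~df["water"].isin(WATER_LEVELS)
    if bad_water.any():
        row = int(df.index[bad_water][0])
        raise ValueError(
            f"row {row}: unknown water level {df.loc[row, 'water']!r} "
            f"(expected one of {WATER_LEVELS})"
        )
    bad_soil = ~df["soil"].isin(SOIL_TYPES)
    if bad_soil.any():
        row = int(df.index[bad_soil][0])
        raise ValueError(
            f"row {row}: unknown soil type {df.loc[row, 'soil']!r} "
            f"(expected one of {SOIL_TYPES})"
        )
    return frame_to_plots(df)


def save_phenotypes(plots: list[PlotObservation], path) -> None:
    plots_to_frame(plots).to_csv(path, index=False)
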