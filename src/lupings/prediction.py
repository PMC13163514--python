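"""Genomic prediction: rrBLUP, GBLUP, weighted GBLUP, cross-validation.

The prediction model is the standard single-trait homoscedastic-marker mixed
model

    y = 1 mu + W u + e,     u ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I),

where ``W`` is the allele-frequency-centered dosage matrix (column k centered
at twice the training allele frequency) and the shrinkage parameter
``lambda = sigma_e^2 / sigma_u^2`` is estimated by restricted maximum
likelihood through the spectral decomposition of ``W W'``.  The equivalent
GBLUP formulation operates on the genomic relationship matrix; the weighted
variant (WGBLUP) scales marker contributions by weights derived from an
initial rrBLUP fit, letting large-effect markers escape uniform shrinkage.

Predictive ability is the Pearson correlation between genomically predicted
and observed genotype means in seeded k-fold cross-validation, the field's
standard intra-environment accuracy measure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .matrix import GenotypeMatrix

__all__ = [
    "GSModel",
    "BreedingValueSet",
    "PredictiveAbilityResult",
    "fit_rrblup",
    "predict_gebv",
    "make_grm",
    "fit_wgblup",
    "cross_validate",
    "adjusted_yield",
]


@dataclass
class GSModel:
    """A fitted whole-genome regression model.

    ``marker_effects`` are additive allele-substitution effects (trait units
    per copy of the minor allele); ``center_freqs`` are the training allele
    frequencies used to center dosages at fit time and reused verbatim at
    prediction time; ``lam`` is the residual-to-marker variance ratio.
    ``marker_weights`` is present only for the weighted (WGBLUP) variant and
    averages 1 over markers.
    """

    intercept: float
    marker_effects: np.ndarray
    lam: float
    marker_ids: list[str]
    center_freqs: np.ndarray
    marker_weights: np.ndarray | None = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.marker_effects = np.asarray(self.marker_effects, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.marker_effects.shape != (len(self.marker_ids),):
            raise ValueError("marker_effects length must equal marker count")
        if self.center_freqs.shape != (len(self.marker_ids),):
            raise ValueError("center_freqs length must equal marker count")
        if not self.lam > 0:
            raise ValueError("shrinkage lambda must be positive")
        if self.marker_weights is not None:
            self.marker_weights = np.asarray(self.marker_weights, dtype=float)
            if (self.marker_weights < 0).any():
                raise ValueError("marker weights must be non-negative")

    def to_json(self, path) -> None:
        payload = {
            "trait": self.trait,
            "intercept": self.intercept,
            "lambda": None if np.isinf(self.lam) else self.lam,
            "marker_ids": self.marker_ids,
            "marker_effects": self.marker_effects.tolist(),
            "center_freqs": self.center_freqs.tolist(),
            "marker_weights": (
                None if self.marker_weights is None else self.marker_weights.tolist()
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GSModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            marker_effects=np.array(payload["marker_effects"]),
            lam=np.inf if payload["lambda"] is None else payload["lambda"],
            marker_ids=payload["marker_ids"],
            center_freqs=np.array(payload["center_freqs"]),
            marker_weights=(
                None
                if payload.get("marker_weights") is None
                else np.array(payload["marker_weights"])
            ),
            trait=payload.get("trait", "trait"),
        )


@dataclass
class BreedingValueSet:
    """Per-genotype predicted (or observed) values for one trait.

    ``m`` and ``s`` are the mean and sample standard deviation (n-1
    denominator) over the stored genotypes — the population statistics the
    phenology-window selection rule is phrased in.
    """

    values: pd.Series
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate genotype ids in breeding-value set")

    @property
    def m(self) -> float:
        return float(self.values.mean())

    @property
    def s(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    def genotype_ids(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"genotype": self.values.index, "trait": self.trait, "value": self.values.values}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BreedingValueSet":
        df = pd.read_csv(path)
        traits = df["trait"].unique()
        if len(traits) != 1:
            raise ValueError("breeding-value CSV must contain a single trait")
        return cls(
            values=pd.Series(df["value"].values, index=df["genotype"].astype(str)),
            trait=str(traits[0]),
        )


@dataclass
class PredictiveAbilityResult:
    """Cross-validated predictive ability (Pearson r, per repeat and mean)."""

    r_per_repeat: np.ndarray
    fold_assignments: np.ndarray  # (repeats, n) integer fold labels
    k: int
    seed: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_per_repeat))


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _align_phenotype(geno: GenotypeMatrix, pheno) -> np.ndarray:
    if isinstance(pheno, pd.Series):
        missing = [g for g in geno.genotype_ids if g not in pheno.index]
        if missing:
            raise ValueError(f"phenotype missing for genotypes: {missing[:5]}")
        return pheno.loc[geno.genotype_ids].to_numpy(dtype=float)
    arr = np.asarray(pheno, dtype=float)
    if arr.shape != (geno.n_genotypes,):
        raise ValueError(
            f"phenotype length {arr.shape} does not match {geno.n_genotypes} genotypes"
        )
    return arr


def _centered(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    if np.isnan(geno.dosage).any():
        raise ValueError("genotype matrix contains missing calls; impute first")
    freqs = geno.dosage.mean(axis=0) / 2.0
    return geno.dosage - 2.0 * freqs, freqs


def _reml_lambda(K: np.ndarray, y: np.ndarray) -> float:
    """REML estimate of lambda = sigma_e^2 / sigma_u^2 for y = 1 mu + g + e.

    Works in the (n-1)-dimensional contrast space orthogonal to the
    intercept, where the restricted likelihood is a 1-D function of the
    variance ratio; minimized over log10(lambda) in [-8, 8].
    """
    n = len(y)
    Q = linalg.null_space(np.ones((1, n)))  # n x (n-1), orthonormal
    M = Q.T @ K @ Q
    theta, V = linalg.eigh(M)
    theta = np.clip(theta, 0.0, None)
    eta = V.T @ (Q.T @ y)
    eta2 = eta**2

    def negloglik(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        denom = theta + lam
        # restricted profile log-likelihood (up to constants), negated
        return (n - 1) * np.log(np.sum(eta2 / denom)) + np.sum(np.log(denom))

    res = optimize.minimize_scalar(negloglik, bounds=(-8.0, 8.0), method="bounded")
    return float(10.0**res.x)


def _gblup_solve(
    K: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """GLS intercept and contrast solution alpha = (K + lam I)^-1 (y - mu)."""
    n = len(y)
    H = K + lam * np.eye(n)
    cho = linalg.cho_factor(H, lower=True)
    hinv_y = linalg.cho_solve(cho, y)
    hinv_1 = linalg.cho_solve(cho, np.ones(n))
    mu = float(np.ones(n) @ hinv_y / (np.ones(n) @ hinv_1))
    alpha = linalg.cho_solve(cho, y - mu)
    return mu, alpha


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def fit_rrblup(
    geno: GenotypeMatrix, pheno, lam: float | None = None, trait: str = "trait"
) -> GSModel:
    """Fit ridge-regression BLUP with REML-estimated shrinkage.

    ``pheno`` is a genotype-mean trait vector (array in matrix row order, or
    a Series indexed by genotype id).  Pass ``lam`` to fix the shrinkage
    instead of estimating it.
    """
    y = _align_phenotype(geno, pheno)
    if geno.n_genotypes < 3:
        raise ValueError("need at least 3 genotypes to fit a model")
    W, freqs = _centered(geno)
    if np.var(y) == 0.0:
        return GSModel(
            intercept=float(y[0]),
            marker_effects=np.zeros(geno.n_markers),
            lam=np.inf,
            marker_ids=list(geno.marker_ids),
            center_freqs=freqs,
            trait=trait,
        )
    K = W @ W.T
    if lam is None:
        lam = _reml_lambda(K, y)
    mu, alpha = _gblup_solve(K, y, lam)
    effects = W.T @ alpha
    return GSModel(
        intercept=mu,
        marker_effects=effects,
        lam=lam,
        marker_ids=list(geno.marker_ids),
        center_freqs=freqs,
        trait=trait,
    )


def predict_gebv(model: GSModel, geno_new: GenotypeMatrix) -> BreedingValueSet:
    """Genomically estimated breeding values for new genotypes.

    Dosages are centered with the TRAINING allele frequencies, so a genotype
    sitting exactly at those frequencies predicts to the intercept.
    """
    absent = [m for m in model.marker_ids if m not in set(geno_new.marker_ids)]
    if absent:
        raise ValueError(f"markers absent from prediction set: {absent[:5]}")
    aligned = geno_new.subset(markers=np.array(model.marker_ids))
    if np.isnan(aligned.dosage).any():
        raise ValueError("prediction matrix contains missing calls; impute first")
    W_new = aligned.dosage - 2.0 * model.center_freqs
    values = model.intercept + W_new @ model.marker_effects
    return BreedingValueSet(
        values=pd.Series(values, index=aligned.genotype_ids), trait=model.trait
    )


def make_grm(geno: GenotypeMatrix, weights: np.ndarray | None = None) -> pd.DataFrame:
    """VanRaden genomic relationship matrix, optionally marker-weighted.

    G = W D W' / (2 sum_k p_k (1 - p_k) * mean(d)), with W the
    frequency-centered dosage matrix and D = diag(weights) (identity when
    ``weights`` is None).
    """
    if geno.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes for a relationship matrix")
    W, freqs = _centered(geno)
    if weights is None:
        weights = np.ones(geno.n_markers)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (geno.n_markers,):
        raise ValueError("weights length must equal marker count")
    denom = 2.0 * np.sum(freqs * (1.0 - freqs)) * np.mean(weights)
    if denom == 0.0:
        raise ValueError("all markers monomorphic: relationship denominator is zero")
    G = (W * weights) @ W.T / denom
    return pd.DataFrame(G, index=geno.genotype_ids, columns=geno.genotype_ids)


def fit_wgblup(
    geno: GenotypeMatrix,
    pheno,
    weight_source: GSModel | None = None,
    weights: np.ndarray | None = None,
    lam: float | None = None,
    trait: str = "trait",
) -> GSModel:
    """Fit weighted GBLUP with marker weights from an initial rrBLUP fit.

    Weights default to the squared rrBLUP effects normalized to mean 1
    (``d_k = u_k^2 / mean(u^2)``), so markers with large estimated effects
    contribute more relationship.  With unit weights the fitted breeding
    values coincide with rrBLUP up to numerical tolerance.
    """
    y = _align_phenotype(geno, pheno)
    if geno.n_genotypes < 3:
        raise ValueError("need at least 3 genotypes to fit a model")
    W, freqs = _centered(geno)
    if np.var(y) == 0.0:
        return GSModel(
            intercept=float(y[0]),
            marker_effects=np.zeros(geno.n_markers),
            lam=np.inf,
            marker_ids=list(geno.marker_ids),
            center_freqs=freqs,
            marker_weights=np.ones(geno.n_markers),
            trait=trait,
        )
    if weights is None:
        if weight_source is None:
            weight_source = fit_rrblup(geno, pheno, trait=trait)
        u = weight_source.marker_effects
        msq = np.mean(u**2)
        weights = u**2 / msq if msq > 0 else np.ones(geno.n_markers)
    weights = np.asarray(weights, dtype=float)
    K = (W * weights) @ W.T
    if lam is None:
        lam = _reml_lambda(K, y)
    mu, alpha = _gblup_solve(K, y, lam)
    effects = weights * (W.T @ alpha)
    return GSModel(
        intercept=mu,
        marker_effects=effects,
        lam=lam,
        marker_ids=list(geno.marker_ids),
        center_freqs=freqs,
        marker_weights=weights,
        trait=trait,
    )


# ---------------------------------------------------------------------------
# cross-validation and the phenology-adjusted yield statistic
# ---------------------------------------------------------------------------


def cross_validate(
    geno: GenotypeMatrix,
    pheno,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    model: str = "rrblup",
) -> PredictiveAbilityResult:
    """Repeated seeded k-fold predictive ability.

    Per repeat, genotypes are partitioned into ``k`` folds; the model is
    refit excluding each held-out fold and the Pearson correlation between
    pooled held-out predictions and observations is recorded.
    """
    y = _align_phenotype(geno, pheno)
    n = geno.n_genotypes
    if n < 2 * k:
        raise ValueError(
            f"n={n} genotypes is too few for {k}-fold CV; use k <= {n // 2}"
        )
    fitter = {"rrblup": fit_rrblup, "wgblup": fit_wgblup}.get(model)
    if fitter is None:
        raise ValueError(f"unknown model {model!r}; choose rrblup or wgblup")

    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    r_values = np.empty(repeats)
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k
        assignments[rep] = folds
        preds = np.empty(n)
        for fold in range(k):
            hold = folds == fold
            train = geno.subset(genotypes=~hold)
            fitted = fitter(train, y[~hold])
            preds[hold] = predict_gebv(fitted, geno.subset(genotypes=hold)).values.values
        r_values[rep] = np.corrcoef(preds, y)[0, 1]
    return PredictiveAbilityResult(
        r_per_repeat=r_values, fold_assignments=assignments, k=k, seed=seed
    )


def adjusted_yield(yield_values, flowering_values) -> np.ndarray:
    """Phenology-independent yield: residuals of yield regressed on flowering.

    Removes the component of genotype yield explained by onset of flowering
    (drought escape through earliness), leaving a drought-resistance signal.
    Residuals sum to zero and are orthogonal to the flowering vector.  If
    flowering has zero variance, centered yields are returned with a warning.
    """
    y = np.asarray(yield_values, dtype=float)
    f = np.asarray(flowering_values, dtype=float)
    if y.shape != f.shape:
        raise ValueError("yield and flowering vectors must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 genotypes")
    if np.var(f) == 0.0:
        warnings.warn(
            "flowering has zero variance; returning mean-centered yields",
            stacklevel=2,
        )
        return y - y.mean()
    slope, intercept = np.polyfit(f, y, deg=1)
    return y - (intercept + slope * f)
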