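"""Shared containers and small statistical helpers for the model engines."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("cagewas")

__all__ = [
    "VarianceComponentsUni",
    "VarianceComponentsBi",
    "FitResult",
    "design_matrix",
    "incidence",
    "lrt_covariance",
    "variance_explained",
    "group_genotype_regression",
]


@dataclass(frozen=True)
class VarianceComponentsUni:
    """Variance components of the univariate animal model (trait units^2)."""

    cage: float
    litter: float
    additive: float
    residual: float

    def __post_init__(self):
        if min(self.cage, self.litter, self.additive, self.residual) < 0:
            raise ValueError("variance components must be non-negative")
        if self.total <= 0:
            raise ValueError("total variance must be positive")

    @property
    def total(self) -> float:
        return self.cage + self.litter + self.additive + self.residual

    def as_array(self) -> np.ndarray:
        return np.array([self.cage, self.litter, self.additive, self.residual])


@dataclass(frozen=True)
class VarianceComponentsBi:
    """Components of the bivariate model; trait 2 is the allele content."""

    g11: float          # additive variance, performance trait
    g12: float          # additive covariance (0 under the null)
    g22: float          # additive variance, allele content
    residual1: float
    residual2: float
    cage: float = 0.0   # trait-1 only
    litter: float = 0.0
    mu: float = float("nan")  # fitted allele-content mean

    def __post_init__(self):
        if min(self.g11, self.g22, self.residual1, self.cage, self.litter) < 0:
            raise ValueError("variances must be non-negative")
        if self.residual2 <= 0:
            raise ValueError("allele-content residual variance must be > 0")

    @property
    def G0(self) -> np.ndarray:
        return np.array([[self.g11, self.g12], [self.g12, self.g22]])


@dataclass
class FitResult:
    """Outcome of one model fit."""

    converged: bool
    n_iter: int
    loglik: float
    varcomp: object
    beta: Optional[np.ndarray] = None
    beta_names: Optional[tuple] = None
    alpha: float = float("nan")
    alpha_se: float = float("nan")
    freq: float = float("nan")
    loglik_path: tuple = field(default_factory=tuple, repr=False)

    def __post_init__(self):
        if self.converged and not np.isfinite(self.loglik):
            raise ValueError("converged fit must have a finite log-likelihood")


def design_matrix(
    frame: pd.DataFrame, factors: Sequence[str], *, intercept: bool = True
):
    """Full-rank fixed-effect design: intercept + drop-first dummies.

    Factor columns with a single level contribute nothing beyond the
    intercept.  Returns ``(X, column_names)``.
    """
    cols = [np.ones(len(frame))] if intercept else []
    names = ["intercept"] if intercept else []
    for f in factors:
        levels = pd.unique(frame[f])
        for lev in levels[1:]:
            cols.append((frame[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return X, tuple(names)


def incidence(labels: Sequence, *, weights=None):
    """0/1 (or weighted) incidence matrix mapping records to factor levels.

    Returns ``(Z, levels)`` where Z is records x levels.
    """
    labels = list(labels)
    levels = list(dict.fromkeys(labels))
    idx = {l: j for j, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, float)
    for i, l in enumerate(labels):
        Z[i, idx[l]] += w[i]
    return Z, tuple(levels)


def lrt_covariance(fit_alt: FitResult, fit_null: FitResult):
    """Likelihood-ratio test of the genetic covariance: ``max(0, 2 * delta)``
    against chi-squared with one degree of freedom."""
    delta = fit_alt.loglik - fit_null.loglik
    if delta < 0:
        if delta < -1e-6:
            warnings.warn(
                f"negative LRT increment {2 * delta:.3g} clamped to 0",
                stacklevel=2,
            )
        delta = 0.0
    stat = 2.0 * delta
    return stat, float(stats.chi2.sf(stat, df=1))


def variance_explained(alpha: float, f: float, sigma_p2: float) -> float:
    """Fraction of phenotypic variance attributed to one SNP:
    ``2 f (1 - f) alpha^2 / sigma_p2``."""
    if not 0.0 < f < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    if sigma_p2 <= 0:
        raise ValueError("phenotypic variance must be > 0")
    return 2.0 * f * (1.0 - f) * alpha**2 / sigma_p2


def cage_mean_genotype(cage_pheno, G, snp_id):
    """Per-cage mean allele content over *genotyped* members.

    Cages without any genotyped member get NaN.  Returns a vector aligned
    with ``cage_pheno.frame`` rows — the regressor for
    :func:`group_genotype_regression`.
    """
    col = G.values[:, G.snp_ids.index(snp_id)]
    sample = {str(a): i for i, a in enumerate(G.sample_ids)}
    out = []
    for cage in cage_pheno.frame["cage"]:
        calls = [
            col[sample[str(a)]]
            for a in cage_pheno.members[cage]
            if str(a) in sample
        ]
        calls = [c for c in calls if np.isfinite(c)]
        out.append(float(np.mean(calls)) if calls else float("nan"))
    return np.array(out)


def group_genotype_regression(
    cage_trait: pd.Series | np.ndarray,
    cage_mean_genotype: pd.Series | np.ndarray,
):
    """OLS of a cage-mean trait on the cage-average genotype (with intercept).

    Returns ``(slope, se, p)`` with the p-value from the slope t-test.
    A constant genotype raises ``ValueError``.
    """
    y = np.asarray(cage_trait, dtype=float)
    x = np.asarray(cage_mean_genotype, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 cages for the regression")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        raise ValueError("cage-average genotype is constant: slope undefined")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    resid = y - y.mean() - slope * (x - x.mean())
    dof = len(y) - 2
    s2 = np.sum(resid**2) / dof
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), df=dof)
    return float(slope), float(se), float(p)
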