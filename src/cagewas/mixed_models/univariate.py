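"""Per-SNP regression on allele content for individually recorded traits.

The model for a record ``y`` is fixed effects (batch, parity, litter-size
class, cage-size class, optionally the SNP allele content) plus independent
cage and litter random effects, an additive genetic effect with covariance
proportional to the numerator relationship matrix, and an iid residual.
Variance components are estimated by maximum likelihood (profiled over the
fixed effects) with an analytic gradient.

``scan_model1`` offers two modes: ``exact`` refits the variance components
per SNP under the alternative; ``emmax`` estimates them once under the
global null and performs generalised least squares per SNP.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from ..pedigree import RelationshipMatrix, subset_A
from .common import FitResult, VarianceComponentsUni, design_matrix, incidence

log = logging.getLogger("cagewas")

__all__ = ["fit_model1", "scan_model1"]

FIXED_FACTORS = ("batch", "parity", "litter_size_class", "cage_size_class")

_LOG_LOWER = -18.0  # log-variance lower bound relative to the trait variance


def _loglik_and_grad(logv, y, X, Ks, *, reml):
    """Profiled (over beta) Gaussian log-likelihood and gradient in log
    variance components.  ``Ks`` are the covariance structures, residual
    identity last."""
    v = np.exp(logv)
    n, p = X.shape
    V = sum(vk * K for vk, K in zip(v, Ks))
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(v)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViX = cho_solve(cho, X)
    Viy = cho_solve(cho, y)
    B = X.T @ ViX
    try:
        beta = np.linalg.solve(B, X.T @ Viy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(B, X.T @ Viy, rcond=None)[0]
    r = y - X @ beta
    Vir = cho_solve(cho, r)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vir)
    Vi = cho_solve(cho, np.eye(n))
    if reml:
        sign, logdetB = np.linalg.slogdet(B)
        ll += -0.5 * logdetB + 0.5 * p * np.log(2 * np.pi)
        # P = Vi - ViX B^-1 X'Vi enters the REML trace term
        try:
            M = np.linalg.solve(B, ViX.T)
        except np.linalg.LinAlgError:
            M = np.linalg.lstsq(B, ViX.T, rcond=None)[0]
        T = Vi - ViX @ M
    else:
        T = Vi
    grad = np.empty_like(v)
    for k, K in enumerate(Ks):
        grad[k] = -0.5 * (np.sum(T * K) - Vir @ K @ Vir) * v[k]
    return -ll, -grad


def _prepare(pheno, A: RelationshipMatrix):
    frame = pheno.frame if hasattr(pheno, "frame") else pheno
    y = frame["adg"].to_numpy(dtype=float)
    animals = [str(a) for a in frame["animal"]]
    A_sub = subset_A(A, animals)
    X0, names = design_matrix(frame, FIXED_FACTORS)
    Zc, _ = incidence(frame["cage"])
    Zl, _ = incidence(frame["litter"])
    Ks = [Zc @ Zc.T, Zl @ Zl.T, A_sub.values, np.eye(len(y))]
    return y, X0, names, Ks


def _optimize_vc(y, X, Ks, *, reml, start=None):
    var_y = max(np.var(y), 1e-12)
    if start is None:
        start = np.full(4, var_y / 4.0)
    logv0 = np.log(np.maximum(start, var_y * np.exp(_LOG_LOWER)))
    bounds = [(np.log(var_y) + _LOG_LOWER, np.log(var_y) + 6.0)] * 4
    logv0 = np.clip(logv0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(
        lambda lv: _loglik_and_grad(lv, y, X, Ks, reml=reml),
        logv0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res


def fit_model1(
    pheno,
    snp: Optional[Sequence[float]] = None,
    A: RelationshipMatrix = None,
    *,
    with_snp: bool = True,
    reml: bool = False,
    start: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the animal model, optionally with the SNP allele-content regression.

    ``pheno`` is an ``IndividualPhenotypes`` (or equivalent frame) for
    genotyped animals only; ``snp`` is the allele-content vector aligned
    with its rows (missing calls are mean-imputed).  Maximum likelihood by
    default; ``reml=True`` switches the criterion.
    """
    y, X, names, Ks = _prepare(pheno, A)
    if with_snp:
        if snp is None:
            raise ValueError("with_snp=True requires an allele-content vector")
        s = np.asarray(snp, dtype=float).copy()
        if np.isnan(s).any():
            s[np.isnan(s)] = np.nanmean(s)
        X = np.column_stack([X, s])
        names = names + ("snp",)
    res = _optimize_vc(y, X, Ks, reml=reml, start=start)
    v = np.exp(res.x)
    vc = VarianceComponentsUni(cage=v[0], litter=v[1], additive=v[2], residual=v[3])
    # GLS solution and SE at the optimum
    V = sum(vk * K for vk, K in zip(v, Ks))
    cho = cho_factor(V, lower=True)
    ViX = cho_solve(cho, X)
    B = X.T @ ViX
    rank_ok = np.linalg.matrix_rank(B) == B.shape[0]
    if not rank_ok:
        log.warning("fit_model1: rank-deficient fixed effects, using pseudo-inverse")
        Binv = np.linalg.pinv(B)
    else:
        Binv = np.linalg.inv(B)
    beta = Binv @ (X.T @ cho_solve(cho, y))
    alpha = float(beta[-1]) if with_snp else float("nan")
    alpha_se = float(np.sqrt(Binv[-1, -1])) if with_snp else float("nan")
    return FitResult(
        converged=bool(res.success),
        n_iter=int(res.nit),
        loglik=float(-res.fun),
        varcomp=vc,
        beta=beta,
        beta_names=names,
        alpha=alpha,
        alpha_se=alpha_se,
    )


def scan_model1(
    pheno,
    G,
    snp_map,
    A: RelationshipMatrix,
    *,
    mode: str = "emmax",
    reml: bool = False,
    trait: str = "adg",
) -> pd.DataFrame:
    """Genome scan under model 1.  Returns one association row per SNP.

    ``mode='exact'`` refits variance components per SNP (slower, mirrors a
    per-SNP ML refit); ``mode='emmax'`` freezes the null-model covariance
    and tests each SNP by GLS.  Monomorphic SNPs are skipped with a log
    entry.
    """
    if mode not in ("exact", "emmax"):
        raise ValueError("mode must be 'exact' or 'emmax'")
    frame = pheno.frame if hasattr(pheno, "frame") else pheno
    sample_index = {str(a): i for i, a in enumerate(G.sample_ids)}
    try:
        rows = [sample_index[str(a)] for a in frame["animal"]]
    except KeyError as exc:
        raise KeyError(f"animal {exc.args[0]!r} has no genotype row") from exc
    Gv = G.values[rows, :]

    y, X0, _, Ks = _prepare(pheno, A)
    null = _optimize_vc(y, X0, Ks, reml=reml)
    v0 = np.exp(null.x)
    ll_null = float(-null.fun)

    V0 = sum(vk * K for vk, K in zip(v0, Ks))
    cho0 = cho_factor(V0, lower=True)
    Vi = cho_solve(cho0, np.eye(len(y)))
    ViX = Vi @ X0
    B0inv = np.linalg.inv(X0.T @ ViX)
    P0 = Vi - ViX @ B0inv @ ViX.T
    P0y = P0 @ y

    records = []
    freqs = G.freq
    for j in range(G.n_snps):
        s = Gv[:, j].copy()
        if np.isnan(s).any():
            if np.all(np.isnan(s)):
                log.info("scan_model1: SNP %s all-missing, skipped", G.snp_ids[j])
                continue
            s[np.isnan(s)] = 2.0 * freqs[j]
        if np.var(s) == 0.0:
            log.info("scan_model1: SNP %s monomorphic, skipped", G.snp_ids[j])
            continue
        if mode == "emmax":
            den = s @ (P0 @ s)
            num = s @ P0y
            alpha = num / den
            se = 1.0 / np.sqrt(den)
            lrt = num**2 / den
        else:
            alt = fit_model1(
                pheno, s, A, with_snp=True, reml=reml, start=v0
            )
            alpha, se = alt.alpha, alt.alpha_se
            lrt = max(0.0, 2.0 * (alt.loglik - ll_null))
        p = float(stats.chi2.sf(lrt, df=1))
        f = float(np.nanmean(Gv[:, j]) / 2.0)
        records.append(
            {
                "snp_id": G.snp_ids[j],
                "chromosome": (
                    snp_map.chromosome[j] if snp_map is not None else "0"
                ),
                "position_bp": (
                    int(snp_map.position_bp[j]) if snp_map is not None else 0
                ),
                "effect": float(alpha),
                "se": float(se),
                "lrt": float(lrt),
                "p": p,
                "method": "model1",
                "trait": trait,
                "freq": f,
                "maf": min(f, 1.0 - f),
            }
        )
    return pd.DataFrame(records)
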