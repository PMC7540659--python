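"""Generic EM-REML engine in the observation (V) representation.

The model is ``y = X beta + sum_k u_k + e`` with each scalar random effect
``u_k ~ N(0, theta_k K_k)`` entering the phenotypic covariance as
``theta_k S_k`` (``S_k = Z_k K_k Z_k'`` precomputed once), an optional
2x2-coupled genetic block ``[a1; a2] ~ N(0, G0 (x) A)`` and grouped
heteroscedastic residuals (``var(e_i) = theta_g / w_i``; a cage-mean record
averaging N animals has weight N).

Each EM step solves the generalised-least-squares problem for the current
covariance, takes conditional expectations of the sufficient statistics
(algebraically identical to the mixed-model-equation solutions plus traces
of the inverse coefficient matrix) and maximises the complete-data
likelihood.  Plain EM steps are interleaved with SQUAREM extrapolation;
an extrapolated candidate is only accepted when it does not lower the
restricted log-likelihood, so the recorded likelihood path never
decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import lapack

log = logging.getLogger("cagewas")

__all__ = ["ScalarComponent", "GeneticBlock", "ResidualGroup", "EmFit", "em_reml"]


@dataclass
class ScalarComponent:
    """One variance component: covariance contribution ``theta * S``."""

    name: str
    S: np.ndarray  # n x n structure matrix Z K Z'
    q: int         # dimension of K (number of effect levels)


@dataclass
class GeneticBlock:
    """Coupled two-trait additive block with covariance ``G0 (x) A``.

    Records must be ordered trait 1 first (n1 rows) then trait 2; the S
    blocks are ``Z_t A Z_s'`` over the respective record sets.
    """

    S11: np.ndarray
    S12: np.ndarray
    S22: np.ndarray
    q: int  # number of animals in A


@dataclass
class ResidualGroup:
    name: str
    idx: np.ndarray       # record indices of this group
    weights: np.ndarray   # var(e_i) = theta / weights_i
    floor: float = 0.0


@dataclass
class EmFit:
    theta: dict                      # scalar component + residual values
    g: Optional[tuple]               # (g11, g12, g22) when a genetic block is present
    beta: np.ndarray
    loglik: float
    loglik_path: tuple = field(repr=False, default=())
    converged: bool = False
    n_iter: int = 0                  # number of EM-map evaluations


def _inv_psd(V: np.ndarray):
    """Inverse and log-determinant of a symmetric PD matrix via Cholesky."""
    c, info = lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"covariance not positive definite (info={info})")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    Vi = np.tril(inv) + np.tril(inv, -1).T
    return Vi, logdet


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    components: Sequence[ScalarComponent],
    resid_groups: Sequence[ResidualGroup],
    genetic: Optional[GeneticBlock] = None,
    n1: Optional[int] = None,
    *,
    theta0: dict,
    g0: Optional[tuple] = None,
    g12_free: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
    scales: Optional[dict] = None,
    accelerate: bool = True,
    ll_tol: float = 1e-8,
) -> EmFit:
    """Run (SQUAREM-accelerated) EM-REML.

    Convergence: the relative change of every variance component over one
    plain EM step falls below ``tol`` (each change measured against
    ``max(theta_k, tol * scale_k)`` so components decaying to zero
    terminate), or the restricted log-likelihood increment of a plain step
    drops below ``ll_tol * (1 + |loglik|)``.

    ``theta0`` maps component and residual-group names to starting values
    (must be positive); ``g0`` starts the genetic block; ``scales`` gives a
    per-parameter variance scale (genetic block under g11/g12/g22).
    ``g12_free=False`` pins the genetic covariance at zero (the null
    model).  Non-convergence within ``max_iter`` EM-map evaluations returns
    a flagged result, never an exception.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if genetic is not None and n1 is None:
        raise ValueError("genetic block requires n1 (records of trait 1)")
    scales = dict(scales or {})
    default_scale = float(np.var(y)) or 1.0

    names = [c.name for c in components]
    if genetic is not None:
        names += ["g11", "g12", "g22"]
    names += [rg.name for rg in resid_groups]
    n_scalar = len(components)
    scale_vec = np.array([scales.get(k, default_scale) for k in names])

    def pack() -> np.ndarray:
        vec = [theta0[c.name] for c in components]
        if genetic is not None:
            g = g0 if g0 is not None else (default_scale / 2, 0.0, default_scale / 2)
            vec += [g[0], 0.0 if not g12_free else g[1], g[2]]
        vec += [theta0[rg.name] for rg in resid_groups]
        return np.array(vec, dtype=float)

    def clamp(vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        for k in range(len(out)):
            nm = names[k]
            if nm == "g12":
                if not g12_free:
                    out[k] = 0.0
                continue
            out[k] = max(out[k], 0.0)
        for j, rg in enumerate(resid_groups):
            k = len(names) - len(resid_groups) + j
            out[k] = max(out[k], rg.floor, 1e-12 * scale_vec[k])
        if genetic is not None and g12_free:
            i11, i12, i22 = n_scalar, n_scalar + 1, n_scalar + 2
            lim = 0.999 * np.sqrt(max(out[i11] * out[i22], 0.0))
            out[i12] = np.clip(out[i12], -lim, lim)
        return out

    rvar = np.empty(n)

    def em_step(vec: np.ndarray):
        """One EM map evaluation: returns (new_vec, loglik_at_vec, beta)."""
        V = np.zeros((n, n))
        for k, comp in enumerate(components):
            if vec[k] != 0.0:
                V += vec[k] * comp.S
        if genetic is not None:
            g11, g12, g22 = vec[n_scalar : n_scalar + 3]
            V[:n1, :n1] += g11 * genetic.S11
            V[:n1, n1:] += g12 * genetic.S12
            V[n1:, :n1] += g12 * genetic.S12.T
            V[n1:, n1:] += g22 * genetic.S22
        off = n_scalar + (3 if genetic is not None else 0)
        for j, rg in enumerate(resid_groups):
            rvar[rg.idx] = vec[off + j] / rg.weights
        V[np.diag_indices_from(V)] += rvar

        Vi, logdetV = _inv_psd(V)
        ViX = Vi @ X
        B = X.T @ ViX
        sign, logdetB = np.linalg.slogdet(B)
        try:
            beta = np.linalg.solve(B, ViX.T @ y)
            M = np.linalg.solve(B, ViX.T)
        except np.linalg.LinAlgError:
            log.warning("em_reml: rank-deficient fixed effects, using pseudo-inverse")
            Binv = np.linalg.pinv(B)
            beta = Binv @ (ViX.T @ y)
            M = Binv @ ViX.T
        P = Vi - ViX @ M
        w = P @ y
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetB + y @ w)

        new = np.empty_like(vec)
        for k, comp in enumerate(components):
            th = vec[k]
            wSw = w @ comp.S @ w
            trPS = float(np.sum(P * comp.S))
            new[k] = (th * th * (wSw - trPS) + th * comp.q) / comp.q
        if genetic is not None:
            w1, w2 = w[:n1], w[n1:]
            d11 = w1 @ genetic.S11 @ w1 - float(np.sum(P[:n1, :n1] * genetic.S11))
            d12 = w1 @ genetic.S12 @ w2 - float(np.sum(P[:n1, n1:] * genetic.S12))
            d22 = w2 @ genetic.S22 @ w2 - float(np.sum(P[n1:, n1:] * genetic.S22))
            qa = genetic.q
            e11 = g11 * g11 * d11 + 2 * g11 * g12 * d12 + g12 * g12 * d22 + g11 * qa
            e22 = g12 * g12 * d11 + 2 * g12 * g22 * d12 + g22 * g22 * d22 + g22 * qa
            new[n_scalar] = e11 / qa
            new[n_scalar + 2] = e22 / qa
            if g12_free:
                e12 = (
                    g11 * g12 * d11
                    + (g11 * g22 + g12 * g12) * d12
                    + g12 * g22 * d22
                    + g12 * qa
                )
                new[n_scalar + 1] = e12 / qa
            else:
                new[n_scalar + 1] = 0.0
        pdiag = np.diag(P)
        for j, rg in enumerate(resid_groups):
            th = vec[off + j]
            pe = (w[rg.idx] ** 2 - pdiag[rg.idx]) / rg.weights
            new[off + j] = max(th + th * th * np.sum(pe) / len(rg.idx), rg.floor)
        return new, float(ll), beta

    def rel_change(a: np.ndarray, b: np.ndarray) -> float:
        return float(
            np.max(np.abs(a - b) / np.maximum(np.abs(b), tol * scale_vec))
        )

    cur = clamp(pack())
    ll_path: list = []
    beta = np.zeros(p)
    evals = 0
    converged = False
    while evals < max_iter and not converged:
        t1, ll0, beta = em_step(cur)
        t1 = clamp(t1)
        evals += 1
        ll_path.append(ll0)
        if evals >= max_iter:
            cur = t1
            break
        t2, ll1, beta = em_step(t1)
        t2 = clamp(t2)
        evals += 1
        ll_path.append(ll1)
        if rel_change(t2, t1) < tol or ll1 - ll0 < ll_tol * (1.0 + abs(ll1)):
            cur = t2
            converged = True
            break
        if not accelerate:
            cur = t2
            continue
        r = t1 - cur
        v = (t2 - t1) - r
        nv = float(np.linalg.norm(v))
        if nv == 0.0:
            cur = t2
            continue
        alpha = min(-float(np.linalg.norm(r)) / nv, -1.0)
        cand = clamp(cur - 2.0 * alpha * r + alpha * alpha * v)
        try:
            t3, ll2, beta2 = em_step(cand)
        except np.linalg.LinAlgError:
            cur = t2
            continue
        evals += 1
        if ll2 >= ll1 - 1e-10:
            ll_path.append(ll2)
            cur = clamp(t3)
            beta = beta2
        else:
            cur = t2  # extrapolation rejected; keep the plain EM iterate

    theta = {
        nm: float(val)
        for nm, val in zip(names, cur)
        if nm not in ("g11", "g12", "g22")
    }
    g = None
    if genetic is not None:
        g = tuple(float(x) for x in cur[n_scalar : n_scalar + 3])
    return EmFit(
        theta=theta,
        g=g,
        beta=beta,
        loglik=float(ll_path[-1]) if ll_path else float("nan"),
        loglik_path=tuple(ll_path),
        converged=converged,
        n_iter=evals,
    )
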