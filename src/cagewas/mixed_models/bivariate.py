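"""Bivariate "allele content as a trait" animal model, fitted by EM-REML.

Trait 1 is a performance trait — individual records, or cage averages when
only the group mean is observable.  Trait 2 is the SNP allele content,
recorded only for genotyped animals and modelled as overall mean plus
additive genetic effect plus residual.  The two traits share a genetic
covariance ``G0 (x) A`` over every animal with records, which is what lets
non-genotyped cage members contribute; the per-SNP effect is recovered as

    alpha = g12 / (2 f (1 - f))

from the estimated genetic covariance ``g12`` and the observed allele
frequency ``f`` among genotyped animals.  A cage-average row enters the
trait-1 equations with weight ``1/N`` on each member's additive and litter
effect and residual variance ``sigma_e1^2 / N``; the residual covariance
between traits is fixed at zero.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..pedigree import RelationshipMatrix, subset_A
from .common import FitResult, VarianceComponentsBi, design_matrix, incidence
from .emreml import GeneticBlock, ResidualGroup, ScalarComponent, em_reml

log = logging.getLogger("cagewas")

__all__ = ["BivariateModel", "fit_bivariate", "scan_bivariate"]

INDIVIDUAL_FACTORS = ("batch", "parity", "litter_size_class", "cage_size_class")
CAGE_FACTORS = ("batch", "cage_size_class")


class BivariateModel:
    """Precomputed design for one trait-1 dataset; reusable across SNPs."""

    def __init__(
        self,
        *,
        y1: np.ndarray,
        X1: np.ndarray,
        Z1: np.ndarray,
        Zl: Optional[np.ndarray],
        Zc: Optional[np.ndarray],
        w1: np.ndarray,
        A_sub: RelationshipMatrix,
        genotyped_ids: Sequence,
        em_tol: float = 1e-6,
        em_max_iter: int = 500,
        em_ll_tol: float = 1e-8,
        se2_floor_frac: float = 1e-4,
        freq_from_mu: bool = False,
    ):
        self.y1 = np.asarray(y1, dtype=float)
        self.X1 = X1
        self.w1 = np.asarray(w1, dtype=float)
        self.n1 = len(self.y1)
        self.A = A_sub
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.em_ll_tol = em_ll_tol
        self.se2_floor_frac = se2_floor_frac
        self.freq_from_mu = freq_from_mu

        index = {a: i for i, a in enumerate(A_sub.ids)}
        self.genotyped_ids = [str(g) for g in genotyped_ids]
        gidx = np.array([index[g] for g in self.genotyped_ids], dtype=int)
        Av = A_sub.values
        Z1A = Z1 @ Av
        self.S11 = Z1A @ Z1.T
        self.S12_all = Z1A[:, gidx]
        self.S22_all = Av[np.ix_(gidx, gidx)]
        self.q_a = len(A_sub)
        self.Sc = None if Zc is None else Zc @ Zc.T
        self.q_c = None if Zc is None else Zc.shape[1]
        self.Sl = None if Zl is None else Zl @ Zl.T
        self.q_l = None if Zl is None else Zl.shape[1]
        self._null1_cache = None
        self._eig2_cache = None  # eigendecomposition of S22_all (complete mask)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_individual(
        cls,
        pheno,
        A: RelationshipMatrix,
        genotyped_ids: Sequence,
        *,
        trait: str = "adg",
        **opts,
    ) -> "BivariateModel":
        """Individual records from genotyped and non-genotyped animals alike."""
        frame = pheno.frame if hasattr(pheno, "frame") else pheno
        animals = [str(a) for a in frame["animal"]]
        universe = list(dict.fromkeys(animals + [str(g) for g in genotyped_ids]))
        A_sub = subset_A(A, universe)
        index = {a: i for i, a in enumerate(universe)}
        n1 = len(frame)
        Z1 = np.zeros((n1, len(universe)))
        Z1[np.arange(n1), [index[a] for a in animals]] = 1.0
        X1, _ = design_matrix(frame, INDIVIDUAL_FACTORS)
        Zc, _ = incidence(frame["cage"])
        Zl, _ = incidence(frame["litter"])
        return cls(
            y1=frame[trait].to_numpy(dtype=float),
            X1=X1,
            Z1=Z1,
            Zl=Zl,
            Zc=Zc,
            w1=np.ones(n1),
            A_sub=A_sub,
            genotyped_ids=genotyped_ids,
            **opts,
        )

    @classmethod
    def from_cage(
        cls,
        cage_pheno,
        individual_meta: pd.DataFrame,
        A: RelationshipMatrix,
        genotyped_ids: Sequence,
        *,
        trait: str,
        **opts,
    ) -> "BivariateModel":
        """Cage-average records; fixed effects are batch and size class only.

        ``individual_meta`` supplies each member's litter for the averaged
        litter effect.
        """
        frame = cage_pheno.frame if hasattr(cage_pheno, "frame") else cage_pheno
        members = cage_pheno.members
        litter_of = dict(
            zip(individual_meta["animal"].astype(str), individual_meta["litter"])
        )
        member_lists = [
            [str(a) for a in members[c]] for c in frame["cage"]
        ]
        universe = list(
            dict.fromkeys(
                [a for ml in member_lists for a in ml]
                + [str(g) for g in genotyped_ids]
            )
        )
        A_sub = subset_A(A, universe)
        index = {a: i for i, a in enumerate(universe)}
        n1 = len(frame)
        Z1 = np.zeros((n1, len(universe)))
        litters = sorted({litter_of[a] for ml in member_lists for a in ml})
        lidx = {l: j for j, l in enumerate(litters)}
        Zl = np.zeros((n1, len(litters)))
        for i, ml in enumerate(member_lists):
            wn = 1.0 / len(ml)
            for a in ml:
                Z1[i, index[a]] += wn
                Zl[i, lidx[litter_of[a]]] += wn
        X1, _ = design_matrix(frame, CAGE_FACTORS)
        return cls(
            y1=frame[trait].to_numpy(dtype=float),
            X1=X1,
            Z1=Z1,
            Zl=Zl,
            Zc=None,
            w1=frame["n_members"].to_numpy(dtype=float),
            A_sub=A_sub,
            genotyped_ids=genotyped_ids,
            **opts,
        )

    # -- component assembly ----------------------------------------------

    def _trait1_parts(self, n_total: int):
        comps = []
        if self.Sc is not None:
            S = np.zeros((n_total, n_total))
            S[: self.n1, : self.n1] = self.Sc
            comps.append(ScalarComponent("cage", S, self.q_c))
        if self.Sl is not None:
            S = np.zeros((n_total, n_total))
            S[: self.n1, : self.n1] = self.Sl
            comps.append(ScalarComponent("litter", S, self.q_l))
        return comps

    def fit_null_trait1(self) -> "em_reml":
        """Univariate EM-REML fit of trait 1 alone (cached; SNP-independent)."""
        if self._null1_cache is not None:
            return self._null1_cache
        n = self.n1
        comps = []
        if self.Sc is not None:
            comps.append(ScalarComponent("cage", self.Sc, self.q_c))
        if self.Sl is not None:
            comps.append(ScalarComponent("litter", self.Sl, self.q_l))
        comps.append(ScalarComponent("a1", self.S11, self.q_a))
        vy = np.var(self.y1)
        theta0 = {c.name: vy / (len(comps) + 1) for c in comps}
        theta0["e1"] = vy / (len(comps) + 1)
        fit = em_reml(
            self.y1,
            self.X1,
            comps,
            [ResidualGroup("e1", np.arange(n), self.w1)],
            theta0=theta0,
            tol=self.em_tol,
            # this fit anchors every SNP's LRT, so converge it extra hard:
            # any shortfall here shifts all test statistics by a constant
            max_iter=max(self.em_max_iter, 2000),
            scales={name: vy for name in list(theta0)},
            ll_tol=min(self.em_ll_tol, 1e-10),
        )
        if not fit.converged:
            log.warning("trait-1 null fit did not converge in %d iterations", fit.n_iter)
        self._null1_cache = fit
        return fit

    def _null2_exact(self, y2: np.ndarray):
        """Exact REML for the allele-content-only model via the cached
        eigendecomposition of A among genotyped animals.

        Maximises the same restricted likelihood the EM engine evaluates
        (identical constants), so the two are interchangeable in LRTs; used
        for complete allele-content vectors, where the decomposition is
        SNP-independent.
        """
        from scipy import optimize

        if self._eig2_cache is None:
            self._eig2_cache = np.linalg.eigh(self.S22_all)
        evals, U = self._eig2_cache
        n2 = len(y2)
        yt = U.T @ y2
        xt = U.T @ np.ones(n2)
        vy = max(float(np.var(y2)), 1e-8)
        floor = self.se2_floor_frac * vy

        def negll(logv):
            va, ve = np.exp(logv)
            d = va * evals + ve
            sxx = np.sum(xt**2 / d)
            sxy = np.sum(xt * yt / d)
            ypy = np.sum(yt**2 / d) - sxy**2 / sxx
            return 0.5 * (
                (n2 - 1) * np.log(2 * np.pi)
                + np.sum(np.log(d))
                + np.log(sxx)
                + ypy
            )

        res = optimize.minimize(
            negll,
            np.log([0.6 * vy, max(0.4 * vy, floor)]),
            method="L-BFGS-B",
            bounds=[(np.log(vy) - 25.0, np.log(vy) + 5.0),
                    (np.log(floor), np.log(vy) + 5.0)],
            options={"maxiter": 200, "ftol": 1e-13},
        )
        va, ve = np.exp(res.x)
        d = va * evals + ve
        mu = float(np.sum(xt * yt / d) / np.sum(xt**2 / d))
        from .emreml import EmFit

        return EmFit(
            theta={"a2": float(va), "e2": float(ve)},
            g=None,
            beta=np.array([mu]),
            loglik=float(-res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
        )

    def fit_null_trait2(
        self, y2: np.ndarray, mask: np.ndarray, theta0=None, *, exact: bool = True
    ):
        """Fit of allele content alone (per SNP).

        Complete vectors use the exact eigendecomposition route by default;
        vectors with missing calls fall back to EM-REML on the submatrix.
        """
        if exact and mask.all():
            return self._null2_exact(y2)
        S22 = self.S22_all[np.ix_(mask, mask)]
        n2 = len(y2)
        vy = max(np.var(y2), 1e-8)
        t0 = dict(theta0) if theta0 else {"a2": 0.6 * vy, "e2": 0.4 * vy}
        # zero starts are EM fixed points; nudge warm starts off the boundary
        t0 = {k: max(v, 1e-4 * vy) for k, v in t0.items()}
        # marginalising the additive effect to genotyped animals leaves the
        # restricted likelihood unchanged and speeds EM up considerably
        return em_reml(
            y2,
            np.ones((n2, 1)),
            [ScalarComponent("a2", S22, n2)],
            [
                ResidualGroup(
                    "e2", np.arange(n2), np.ones(n2),
                    floor=self.se2_floor_frac * vy,
                )
            ],
            theta0=t0,
            tol=self.em_tol,
            max_iter=self.em_max_iter,
            scales={"a2": vy, "e2": vy},
            ll_tol=self.em_ll_tol,
        )

    def fit(
        self,
        snp: Sequence[float],
        *,
        null: bool = False,
        theta0: Optional[dict] = None,
        g0: Optional[tuple] = None,
        t2_theta0: Optional[dict] = None,
    ) -> FitResult:
        """Fit the bivariate model for one SNP.

        ``snp`` is the allele-content vector aligned with the model's
        genotyped ids; missing calls become missing trait-2 records.  Under
        the null the genetic covariance is pinned at zero (the joint
        likelihood then separates into the two univariate fits).  Raises
        ``ValueError`` for SNPs fixed among genotyped animals.
        """
        s = np.asarray(snp, dtype=float)
        mask = np.isfinite(s)
        y2 = s[mask]
        f = float(np.mean(y2)) / 2.0
        if not 0.0 < f < 1.0:
            raise ValueError("SNP fixed among genotyped animals: effect undefined")

        if null:
            f1 = self.fit_null_trait1()
            f2 = self.fit_null_trait2(y2, mask, theta0=t2_theta0)
            vc = VarianceComponentsBi(
                g11=f1.theta["a1"],
                g12=0.0,
                g22=f2.theta["a2"],
                residual1=f1.theta["e1"],
                residual2=f2.theta["e2"],
                cage=f1.theta.get("cage", 0.0),
                litter=f1.theta.get("litter", 0.0),
                mu=float(f2.beta[0]),
            )
            freq = vc.mu / 2.0 if self.freq_from_mu else f
            return FitResult(
                converged=f1.converged and f2.converged,
                n_iter=f1.n_iter + f2.n_iter,
                loglik=f1.loglik + f2.loglik,
                varcomp=vc,
                beta=np.concatenate([f1.beta, f2.beta]),
                alpha=0.0,
                freq=freq,
                loglik_path=tuple(
                    a + b for a, b in zip(f1.loglik_path, f2.loglik_path)
                ),
            )

        n1, n2 = self.n1, len(y2)
        n = n1 + n2
        y = np.concatenate([self.y1, y2])
        X = np.zeros((n, self.X1.shape[1] + 1))
        X[:n1, : self.X1.shape[1]] = self.X1
        X[n1:, -1] = 1.0
        genetic = GeneticBlock(
            S11=self.S11,
            S12=self.S12_all[:, mask],
            S22=self.S22_all[np.ix_(mask, mask)],
            q=self.q_a,
        )
        comps = self._trait1_parts(n)
        vy2 = max(np.var(y2), 1e-8)
        resid = [
            ResidualGroup("e1", np.arange(n1), self.w1),
            ResidualGroup(
                "e2", np.arange(n1, n), np.ones(n2),
                floor=self.se2_floor_frac * vy2,
            ),
        ]
        if theta0 is None or g0 is None:
            # warm start from the separable null fits
            f1 = self.fit_null_trait1()
            f2 = self.fit_null_trait2(y2, mask, theta0=t2_theta0)
            theta0 = {
                name: f1.theta[name]
                for name in ("cage", "litter", "e1")
                if name in f1.theta
            }
            theta0["e2"] = f2.theta["e2"]
            g0 = (f1.theta["a1"], 0.0, f2.theta["a2"])
        vy1 = float(np.var(self.y1)) or 1.0
        theta0 = {
            k: max(v, 1e-4 * (vy2 if k == "e2" else vy1))
            for k, v in theta0.items()
        }
        g0 = (max(g0[0], 1e-4 * vy1), g0[1], max(g0[2], 1e-4 * vy2))
        scales = {name: vy1 for name in ("cage", "litter", "e1")}
        scales.update(
            {"e2": vy2, "g11": vy1, "g22": vy2, "g12": np.sqrt(vy1 * vy2)}
        )
        fit = em_reml(
            y,
            X,
            comps,
            resid,
            genetic=genetic,
            n1=n1,
            theta0=theta0,
            g0=g0,
            tol=self.em_tol,
            max_iter=self.em_max_iter,
            scales=scales,
            ll_tol=self.em_ll_tol,
        )
        if not fit.converged:
            log.warning(
                "bivariate fit not converged after %d iterations", fit.n_iter
            )
        g11, g12, g22 = fit.g
        mu = float(fit.beta[-1])
        freq = mu / 2.0 if self.freq_from_mu else f
        vc = VarianceComponentsBi(
            g11=max(g11, 0.0),
            g12=g12,
            g22=max(g22, 0.0),
            residual1=fit.theta["e1"],
            residual2=fit.theta["e2"],
            cage=fit.theta.get("cage", 0.0),
            litter=fit.theta.get("litter", 0.0),
            mu=mu,
        )
        alpha = g12 / (2.0 * freq * (1.0 - freq))
        return FitResult(
            converged=fit.converged,
            n_iter=fit.n_iter,
            loglik=fit.loglik,
            varcomp=vc,
            beta=fit.beta,
            alpha=float(alpha),
            freq=freq,
            loglik_path=fit.loglik_path,
        )


def fit_bivariate(
    trait1,
    snp: Sequence[float],
    A: RelationshipMatrix,
    genotyped_ids: Sequence,
    *,
    null: bool = False,
    trait: str = "adg",
    individual_meta: Optional[pd.DataFrame] = None,
    **opts,
) -> FitResult:
    """One-shot wrapper: build the design for ``trait1`` and fit one SNP.

    ``trait1`` is an ``IndividualPhenotypes`` or ``CagePhenotypes``; cage
    phenotypes additionally need ``individual_meta`` for member litters.
    """
    if hasattr(trait1, "members"):
        model = BivariateModel.from_cage(
            trait1, individual_meta, A, genotyped_ids, trait=trait, **opts
        )
    else:
        model = BivariateModel.from_individual(
            trait1, A, genotyped_ids, trait=trait, **opts
        )
    return model.fit(snp, null=null)


def scan_bivariate(
    model: BivariateModel,
    G,
    snp_map,
    *,
    trait: str = "adg",
) -> pd.DataFrame:
    """Per-SNP bivariate scan: null and alternative fits, LRT and effect."""
    from .common import lrt_covariance

    sample_index = {str(a): i for i, a in enumerate(G.sample_ids)}
    try:
        rows = [sample_index[g] for g in model.genotyped_ids]
    except KeyError as exc:
        raise KeyError(f"genotyped id {exc.args[0]!r} missing from genotypes") from exc
    Gv = G.values[rows, :]
    records = []
    prev_t2: Optional[dict] = None
    prev_alt: Optional[tuple] = None  # (theta0, (g11, g22)) of last alt fit
    for j in range(G.n_snps):
        s = Gv[:, j]
        try:
            null_fit = model.fit(s, null=True, t2_theta0=prev_t2)
            vc0 = null_fit.varcomp
            theta0 = {"e1": vc0.residual1, "e2": vc0.residual2}
            if model.Sc is not None:
                theta0["cage"] = vc0.cage
            if model.Sl is not None:
                theta0["litter"] = vc0.litter
            alt_fit = model.fit(s, theta0=theta0, g0=(vc0.g11, 0.0, vc0.g22))
            prev_t2 = {"a2": vc0.g22, "e2": vc0.residual2}
        except ValueError:
            log.info("scan_bivariate: SNP %s skipped (fixed)", G.snp_ids[j])
            continue
        lrt, p = lrt_covariance(alt_fit, null_fit)
        f = alt_fit.freq
        records.append(
            {
                "snp_id": G.snp_ids[j],
                "chromosome": (
                    snp_map.chromosome[j] if snp_map is not None else "0"
                ),
                "position_bp": (
                    int(snp_map.position_bp[j]) if snp_map is not None else 0
                ),
                "effect": alt_fit.alpha,
                "se": float("nan"),
                "lrt": float(lrt),
                "p": float(p),
                "method": "bivar",
                "trait": trait,
                "freq": f,
                "maf": min(f, 1.0 - f),
                "converged": alt_fit.converged and null_fit.converged,
            }
        )
    return pd.DataFrame(records)
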