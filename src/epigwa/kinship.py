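"""Genomic kinships and the two-random-effect variance decomposition.

The additive kinship G is the marker-average Gram matrix of per-SNP
standardized genotypes; its Hadamard square G∘G carries the
additive-by-additive epistatic relationships.  The mixed model

    y = mu + a + b + e,   a ~ N(0, G sigma_a^2),   b ~ N(0, G∘G sigma_aa^2)

is fitted by REML with non-negativity bounds, giving the narrow-sense
heritability h2 = sigma_a^2 / sigma_p^2 and the genomic broad-sense
heritability H2 = (sigma_a^2 + sigma_aa^2) / sigma_p^2, with delete-one
jackknife standard errors and one-sided Wald tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, KinshipMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kinships
# ---------------------------------------------------------------------------

def compute_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Additive genomic kinship G = Z Z' / m.

    Each polymorphic SNP column is centered by its panel mean and scaled
    by its population standard deviation (divisor n); missing calls are
    set to the SNP mean (zero after centering).  Monomorphic SNPs are
    skipped with a logged count.
    """
    calls = genotypes.calls.astype(float)
    missing = genotypes.calls == 0
    calls[missing] = np.nan
    mean = np.nanmean(calls, axis=0)
    sd = np.nanstd(calls, axis=0)  # population sd, divisor n
    poly = sd > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("kinship: skipping %d monomorphic SNPs", n_mono)
    if poly.sum() < 2:
        raise ValueError("kinship requires at least 2 polymorphic SNPs")
    Z = (calls[:, poly] - mean[poly]) / sd[poly]
    Z[np.isnan(Z)] = 0.0
    G = Z @ Z.T / poly.sum()
    return KinshipMatrix(genotypes.accession_ids, G)


def epistatic_kinship(G: KinshipMatrix) -> KinshipMatrix:
    """Hadamard square G∘G (PSD by the Schur product theorem)."""
    return G.hadamard_square()


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def reml_neg2_loglik_and_grad(theta: np.ndarray, y: np.ndarray,
                              comps: Tuple[np.ndarray, ...]):
    """-2 x restricted log-likelihood and its gradient.

    ``comps`` are the covariance components (G, G∘G, I); V = sum theta_i
    comps_i and X is the intercept column.  Constant terms are included
    so values are comparable across parameter points.
    """
    n = y.size
    V = sum(t * C for t, C in zip(theta, comps))
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(len(theta))
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vinv = cho_solve((c, low), np.eye(n))
    ones = np.ones(n)
    Vinv1 = Vinv @ ones
    xtvx = float(ones @ Vinv1)
    P = Vinv - np.outer(Vinv1, Vinv1) / xtvx
    Py = P @ y
    yPy = float(y @ Py)
    neg2 = logdetV + np.log(xtvx) + yPy + (n - 1) * np.log(2.0 * np.pi)
    # tr(P C) = sum(P * C) for symmetric C — avoids a full matrix product
    grad = np.array([float((P * C).sum()) - float(Py @ C @ Py)
                     for C in comps])
    return neg2, grad


@dataclass
class VarianceComponents:
    """Fitted variance decomposition of an accession-level trait."""

    mu: float
    sigma2_a: float
    sigma2_aa: float
    sigma2_e: float
    h2: float
    H2: float
    loglik: float
    converged: bool
    se_h2: Optional[float] = None
    se_H2: Optional[float] = None
    p_h2: Optional[float] = None
    p_H2: Optional[float] = None
    se_flagged: bool = False

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.h2 <= self.H2 + 1e-9 <= 1.0 + 1e-9):
            raise ValueError("expected 0 <= h2 <= H2 <= 1")


class EpistaticVarianceModel(BaseEstimator):
    """REML fit of the additive + additive-by-additive mixed model.

    Parameters
    ----------
    boundary_tol : estimates below ``boundary_tol * var(y)`` are reported
        as exactly 0 (the REML optimum sits on the boundary).
    n_starts : number of deterministic starting points.

    Attributes (after :meth:`fit`)
    ------------------------------
    mu_, sigma2_a_, sigma2_aa_, sigma2_e_ : estimates (trait units^2).
    h2_, H2_ : heritability ratios on the accession-level trait.
    loglik_ : restricted log-likelihood at the optimum.
    converged_ : whether any optimizer run converged.
    """

    def __init__(self, boundary_tol: float = 1e-6, n_starts: int = 3,
                 max_iter: int = 200, ftol: float = 1e-9):
        self.boundary_tol = boundary_tol
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.ftol = ftol

    # -- core ----------------------------------------------------------
    def fit(self, X, y, G: Optional[np.ndarray] = None,
            GG: Optional[np.ndarray] = None) -> "EpistaticVarianceModel":
        """Fit to an accession phenotype vector.

        ``X`` may be a :class:`GenotypeMatrix` (kinships are computed),
        an (n, m) call matrix, or None when ``G``/``GG`` are given.
        """
        if G is None:
            gm = X if isinstance(X, GenotypeMatrix) else _matrix_from_calls(X)
            G = compute_kinship(gm).values
        else:
            G = np.asarray(G, dtype=float)
        GG = G * G if GG is None else np.asarray(GG, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if n < 10:
            raise ValueError("variance-component fit requires n >= 10")
        if G.shape != (n, n) or GG.shape != (n, n):
            raise ValueError("kinship dimensions do not match y")

        comps = (G, GG, np.eye(n))
        vy = float(np.var(y))
        if vy == 0.0:
            self._set_estimates(y, comps, np.array([0.0, 0.0, 0.0]),
                                loglik=np.nan, converged=True)
            return self

        floor = 1e-8 * vy
        bounds = [(0.0, None), (0.0, None), (floor, None)]
        starts = [np.array([vy / 3, vy / 3, vy / 3]),
                  np.array([0.02 * vy, 0.02 * vy, 0.96 * vy]),
                  np.array([0.45 * vy, 0.45 * vy, 0.10 * vy])]
        if getattr(self, "_warm_start_theta", None) is not None:
            starts = [np.maximum(self._warm_start_theta,
                                 [0.0, 0.0, floor])] + starts
        starts = starts[: self.n_starts]

        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(
                reml_neg2_loglik_and_grad, x0, args=(y, comps), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.ftol})
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("REML optimization failed on every start")

        theta = np.asarray(best.x, dtype=float)
        theta[theta < self.boundary_tol * vy] = 0.0
        self._set_estimates(y, comps, theta, loglik=-0.5 * best.fun,
                            converged=converged)
        return self

    def _set_estimates(self, y, comps, theta, loglik, converged):
        n = y.size
        sa, saa, se = map(float, theta)
        total = sa + saa + se
        V = sa * comps[0] + saa * comps[1] + max(se, 1e-12) * comps[2]
        Vinv1 = np.linalg.solve(V, np.ones(n))
        self.mu_ = float(Vinv1 @ y / Vinv1.sum())
        self.sigma2_a_, self.sigma2_aa_, self.sigma2_e_ = sa, saa, se
        self.h2_ = sa / total if total > 0 else 0.0
        self.H2_ = (sa + saa) / total if total > 0 else 0.0
        self.loglik_ = loglik
        self.converged_ = converged
        self.n_components_ = 3

    def loglik_at(self, y, G, GG, theta) -> float:
        """Restricted log-likelihood at arbitrary (sigma2_a, sigma2_aa,
        sigma2_e) — exposed for oracle checks."""
        y = np.asarray(y, dtype=float)
        neg2, _ = reml_neg2_loglik_and_grad(
            np.asarray(theta, float), y, (np.asarray(G, float),
                                          np.asarray(GG, float),
                                          np.eye(y.size)))
        return -0.5 * neg2


def _matrix_from_calls(X) -> GenotypeMatrix:
    from .datatypes import SnpInfo
    X = np.asarray(X)
    snps = [SnpInfo(id=f"s{j + 1}", chromosome="0", position=j + 1, maf=0.0)
            for j in range(X.shape[1])]
    ids = [f"a{i + 1}" for i in range(X.shape[0])]
    return GenotypeMatrix(ids, snps, X.astype(np.int8), validate=False)


# ---------------------------------------------------------------------------
# spec-surface wrappers
# ---------------------------------------------------------------------------

def fit_variance_components(y, G, GG=None) -> VarianceComponents:
    """REML variance components for an accession phenotype (thin wrapper
    over :class:`EpistaticVarianceModel`)."""
    G = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, float)
    GG = (GG.values if isinstance(GG, KinshipMatrix)
          else (G * G if GG is None else np.asarray(GG, float)))
    model = EpistaticVarianceModel().fit(None, y, G=G, GG=GG)
    return VarianceComponents(
        mu=model.mu_, sigma2_a=model.sigma2_a_, sigma2_aa=model.sigma2_aa_,
        sigma2_e=model.sigma2_e_, h2=model.h2_, H2=model.H2_,
        loglik=model.loglik_, converged=model.converged_)


def _wald_one_sided(estimate: float, se: float) -> float:
    """One-sided Wald p for a variance-ratio estimate being > 0."""
    if se == 0.0 or not np.isfinite(se):
        return 1.0 if estimate <= 0 else 0.0
    w = (estimate / se) ** 2
    p = 0.5 * stats.chi2.sf(w, df=1)
    return float(p if estimate > 0 else 1.0 - p)


def heritability_summary(y, G, GG=None, max_fail_frac: float = 0.10
                         ) -> VarianceComponents:
    """Variance components with delete-one-accession jackknife SEs and
    one-sided Wald tests for h2 > 0 and H2 > 0."""
    G = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, float)
    GG = (GG.values if isinstance(GG, KinshipMatrix)
          else (G * G if GG is None else np.asarray(GG, float)))
    y = np.asarray(y, dtype=float)
    n = y.size

    model = EpistaticVarianceModel().fit(None, y, G=G, GG=GG)
    vc = VarianceComponents(
        mu=model.mu_, sigma2_a=model.sigma2_a_, sigma2_aa=model.sigma2_aa_,
        sigma2_e=model.sigma2_e_, h2=model.h2_, H2=model.H2_,
        loglik=model.loglik_, converged=model.converged_)

    if np.var(y) == 0.0:
        vc.se_h2 = vc.se_H2 = 0.0
        vc.p_h2 = vc.p_H2 = 1.0
        return vc

    warm = np.array([model.sigma2_a_, model.sigma2_aa_, model.sigma2_e_])
    h2s, H2s, failures = [], [], 0
    # warm-started deletions tolerate a coarser optimum: the jackknife SE
    # averages over n refits, so per-refit noise at ftol 1e-6 is negligible
    sub = EpistaticVarianceModel(n_starts=1, max_iter=60, ftol=1e-6)
    sub._warm_start_theta = warm
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        try:
            sub.fit(None, y[keep], G=G[np.ix_(keep, keep)],
                    GG=GG[np.ix_(keep, keep)])
            h2s.append(sub.h2_)
            H2s.append(sub.H2_)
        except Exception:
            failures += 1
    if failures > max_fail_frac * n:
        logger.warning("jackknife: %d/%d deletions failed; SEs flagged",
                       failures, n)
        vc.se_flagged = True
    k = len(h2s)
    h2s, H2s = np.asarray(h2s), np.asarray(H2s)
    vc.se_h2 = float(np.sqrt((k - 1) / k * ((h2s - h2s.mean()) ** 2).sum()))
    vc.se_H2 = float(np.sqrt((k - 1) / k * ((H2s - H2s.mean()) ** 2).sum()))
    vc.p_h2 = _wald_one_sided(vc.h2, vc.se_h2)
    vc.p_H2 = _wald_one_sided(vc.H2, vc.se_H2)
    return vc


# ---------------------------------------------------------------------------
# ANOVA broad-sense heritability
# ---------------------------------------------------------------------------

@dataclass
class AnovaHeritability:
    H2: float
    p: float
    ms_between: float
    ms_within: float
    n0: float  # average group size (unequal-n correction)


def anova_broad_sense(records: pd.DataFrame) -> AnovaHeritability:
    """Broad-sense heritability from one-way ANOVA on accession.

    Between/within variance components use the mean-square method with
    the average group size n0 = (N - sum n_i^2 / N) / (a - 1);
    H2 = sigma_b^2 / (sigma_b^2 + sigma_w^2), with the F-test p-value
    for accession differences.
    """
    groups = [g.to_numpy() for _, g in
              records.groupby("accession_id")["root_length"]]
    a = len(groups)
    if a < 2:
        raise ValueError("ANOVA heritability requires >= 2 accessions")
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = a - 1, int(N) - a
    if df_w < 1:
        raise ValueError("ANOVA heritability requires replicated accessions")
    msb, msw = ssb / df_b, ssw / df_w
    n0 = (N - (sizes ** 2).sum() / N) / df_b
    sigma_b = max((msb - msw) / n0, 0.0)
    H2 = sigma_b / (sigma_b + msw) if (sigma_b + msw) > 0 else 0.0
    F = msb / msw if msw > 0 else np.inf
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaHeritability(H2=float(H2), p=p, ms_between=msb,
                             ms_within=msw, n0=float(n0))
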