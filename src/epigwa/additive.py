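"""Single-marker additive scans.

Two complementary additive analyses: a structure-corrected single-SNP
score test (phenotype and dosages residualized on the leading kinship
eigenvectors), and a whole-genome generalized ridge scan in which all
SNP effects are fitted simultaneously as shrunken random effects with a
second, heteroscedastic per-SNP shrinkage pass (HEM).  The HEM scan's
genome-wide 5% significance threshold comes from the permutation
distribution of the maximum absolute SNP effect.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, KinshipMatrix


def _dosage_matrix(genotypes) -> np.ndarray:
    """Float calls with missing values replaced by the SNP mean."""
    if isinstance(genotypes, GenotypeMatrix):
        calls = genotypes.calls.astype(float)
        miss = genotypes.calls == 0
    else:
        calls = np.asarray(genotypes, dtype=float)
        miss = ~np.isfinite(calls)
    if miss.any():
        calls = calls.copy()
        calls[miss] = np.nan
        mean = np.nanmean(calls, axis=0)
        idx = np.where(miss)
        calls[idx] = mean[idx[1]]
    return calls


# ---------------------------------------------------------------------------
# structure-corrected score scan
# ---------------------------------------------------------------------------

class StructureAdjustedScan(BaseEstimator):
    """Single-SNP score test with eigenvector structure correction.

    The phenotype and every SNP dosage are residualized on the intercept
    plus the top ``n_axes`` eigenvectors of the kinship matrix; each SNP
    then gets a 1-df score statistic, squared correlation x residual df,
    referred to a chi-square(1).

    Attributes (after fit): ``effects_`` (mm per coded-allele unit),
    ``p_values_``, ``df_``, ``m_``.
    """

    def __init__(self, n_axes: int = 3):
        self.n_axes = n_axes

    def fit(self, X, y, K=None) -> "StructureAdjustedScan":
        y = np.asarray(y, dtype=float)
        n = y.size
        if self.n_axes >= n:
            raise ValueError(f"n_axes = {self.n_axes} must be < n = {n}")
        if self.n_axes < 0:
            raise ValueError("n_axes must be >= 0")
        D = _dosage_matrix(X)
        if K is None:
            from .kinship import compute_kinship
            K = compute_kinship(X).values if isinstance(X, GenotypeMatrix) \
                else np.corrcoef(D)
        K = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)

        w, U = np.linalg.eigh(K)
        axes = U[:, ::-1][:, : self.n_axes]
        Q = np.column_stack([np.ones(n), axes])
        H = Q @ np.linalg.pinv(Q)
        yr = y - H @ y
        Dr = D - H @ D

        df = n - self.n_axes - 1
        sy = np.sqrt((yr ** 2).sum())
        sd = np.sqrt((Dr ** 2).sum(axis=0))
        ok = (sd > 0) & (sy > 0)
        corr = np.zeros(D.shape[1])
        corr[ok] = (Dr[:, ok].T @ yr) / (sd[ok] * sy)
        score = corr ** 2 * df
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(sd > 0, (Dr.T @ yr) / np.maximum(sd ** 2, 1e-300),
                            0.0)
        self.effects_ = beta
        self.scores_ = score
        self.p_values_ = stats.chi2.sf(score, df=1)
        self.p_values_[~ok] = 1.0
        self.df_ = df
        self.m_ = D.shape[1]
        return self


def structure_adjusted_scan(y, genotypes, K, n_axes: int = 3
                            ) -> pd.DataFrame:
    """Thin wrapper: per-SNP effects and score-test p-values."""
    scan = StructureAdjustedScan(n_axes=n_axes).fit(genotypes, y, K=K)
    ids = genotypes.snp_ids if isinstance(genotypes, GenotypeMatrix) \
        else [f"s{j + 1}" for j in range(scan.m_)]
    return pd.DataFrame({"snp": ids, "effect": scan.effects_,
                         "score_p": scan.p_values_})


# ---------------------------------------------------------------------------
# HEM ridge scan
# ---------------------------------------------------------------------------

class HemScan(BaseEstimator):
    """Whole-genome generalized ridge scan with heteroscedastic updates.

    Stage 1 fits the SNP-BLUP model y = mu + Z u + e, u ~ N(0, sigma_u^2 I),
    choosing the common shrinkage by REML (eigendecomposition of Z Z').
    Stage 2 re-weights each SNP's prior variance by u_j^2 / (1 - h_jj)
    (effect leverage h_jj from stage 1) and re-solves the ridge system,
    letting large stage-1 effects escape shrinkage.

    Attributes (after fit): ``effects_`` (stage 2), ``effects_stage1_``,
    ``mu_``, ``lambda_`` (sigma_u^2 / sigma_e^2), ``sigma2_e_``.
    """

    def __init__(self, max_log_lambda: float = 12.0):
        self.max_log_lambda = max_log_lambda

    # -- internal: reusable across permutations -------------------------
    def _prepare(self, X) -> None:
        Z = _dosage_matrix(X)
        Z = Z - Z.mean(axis=0)
        self._Z = Z
        K = Z @ Z.T
        self._d, self._U = np.linalg.eigh(K)
        self._d = np.clip(self._d, 0.0, None)

    def _reml_lambda(self, yt, xt):
        """Profile REML over lambda on the rotated SNP-BLUP model."""
        n = yt.size

        def neg2(loglam):
            lam = np.exp(loglam)
            w = lam * self._d + 1.0
            xw = xt / w
            xtwx = float(xt @ xw)
            beta = float(xw @ yt) / xtwx
            r = yt - xt * beta
            S = float(r @ (r / w))
            s2 = S / (n - 1)
            return (n - 1) * np.log(s2) + np.log(w).sum() + np.log(xtwx)

        res = optimize.minimize_scalar(
            neg2, bounds=(-self.max_log_lambda, self.max_log_lambda),
            method="bounded")
        return float(np.exp(res.x))

    def _solve(self, y):
        """Two-stage effects for one phenotype vector (panel fixed)."""
        Z, d, U = self._Z, self._d, self._U
        n, m = Z.shape
        yt = U.T @ y
        xt = U.T @ np.ones(n)
        if np.var(y) < 1e-24 * max(1.0, float(y @ y)):
            zeros = np.zeros(m)
            return zeros, zeros.copy(), float(y.mean()), 0.0, 0.0
        lam = self._reml_lambda(yt, xt)
        w = lam * d + 1.0

        xw = xt / w
        mu = float(xw @ yt) / float(xt @ xw)
        rt = yt - xt * mu                      # rotated residual from mu
        Mr = U @ (rt / w)                      # (lam K + I)^-1 (y - mu)
        u1 = lam * (Z.T @ Mr)

        S = float(rt @ (rt / w))
        sigma2_e = S / (n - 1)

        # effect leverages h_jj = lam * z_j' (lam K + I)^-1 z_j
        MZ = U @ ((U.T @ Z) / w[:, None])
        h = lam * np.einsum("ij,ij->j", Z, MZ)
        h = np.clip(h, 0.0, 1.0 - 1e-12)
        wj = u1 ** 2 / (1.0 - h)

        # stage 2: per-SNP prior variances wj, ridge penalty sigma2_e
        V2 = (Z * wj) @ Z.T + sigma2_e * np.eye(n)
        sol = np.linalg.solve(V2, np.column_stack([y, np.ones(n)]))
        mu2 = float(sol[:, 1] @ y) / float(sol[:, 1].sum())
        u2 = wj * (Z.T @ (sol[:, 0] - mu2 * sol[:, 1]))  # wj Z'V2^-1(y - mu2)
        return u2, u1, mu, lam, sigma2_e

    def fit(self, X, y) -> "HemScan":
        y = np.asarray(y, dtype=float)
        if (np.asarray(X.calls if isinstance(X, GenotypeMatrix) else X)
                .shape[1]) < 2:
            raise ValueError("HEM scan requires at least 2 SNPs")
        self._prepare(X)
        u2, u1, mu, lam, s2e = self._solve(y)
        self.effects_ = u2
        self.effects_stage1_ = u1
        self.mu_ = mu
        self.lambda_ = lam
        self.sigma2_e_ = s2e
        return self

    def permutation_threshold(self, y, n_perm: int = 1000,
                              quantile: float = 0.95,
                              seed: int = 0) -> "PermutationThreshold":
        """Empirical genome-wide threshold on |effect|.

        The phenotype is permuted across accessions ``n_perm`` times, the
        two-stage scan rerun (the genotype eigenstructure is reused), and
        the stated quantile of the permutation maxima returned, together
        with the permutation p-value of the observed maximum.
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not hasattr(self, "effects_"):
            raise RuntimeError("fit the scan before permuting")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            u2, *_ = self._solve(yp)
            maxima[b] = np.abs(u2).max()
        observed = float(np.abs(self.effects_).max())
        thr = float(np.quantile(maxima, quantile))
        p_obs = float((np.sum(maxima >= observed) + 1) / (n_perm + 1))
        return PermutationThreshold(threshold=thr, quantile=quantile,
                                    n_perm=n_perm, observed_max=observed,
                                    p_observed=p_obs)


@dataclass
class PermutationThreshold:
    threshold: float
    quantile: float
    n_perm: int
    observed_max: float
    p_observed: float


def hem_scan(y, genotypes) -> pd.DataFrame:
    """Thin wrapper: stage-2 shrunken effect per SNP."""
    scan = HemScan().fit(genotypes, y)
    ids = genotypes.snp_ids if isinstance(genotypes, GenotypeMatrix) \
        else [f"s{j + 1}" for j in range(len(scan.effects_))]
    return pd.DataFrame({"snp": ids, "hem_effect": scan.effects_,
                         "stage1_effect": scan.effects_stage1_})


def permutation_threshold(y, genotypes, n_perm: int = 1000,
                          quantile: float = 0.95,
                          seed: int = 0) -> PermutationThreshold:
    """Thin wrapper over :meth:`HemScan.permutation_threshold`."""
    scan = HemScan().fit(genotypes, y)
    return scan.permutation_threshold(y, n_perm=n_perm, quantile=quantile,
                                      seed=seed)


# ---------------------------------------------------------------------------
# combined result
# ---------------------------------------------------------------------------

@dataclass
class AdditiveScanResult:
    """Joint per-SNP table of both additive analyses plus thresholds."""

    table: pd.DataFrame                 # snp, chromosome, position,
                                        # effect, score_p, hem_effect
    bonferroni_p: float                 # alpha / m on the score scan
    hem_threshold: Optional[PermutationThreshold] = None

    @property
    def any_significant(self) -> bool:
        hits = (self.table["score_p"] <= self.bonferroni_p).any()
        if self.hem_threshold is not None:
            hits = hits or bool((self.table["hem_effect"].abs()
                                 > self.hem_threshold.threshold).any())
        return bool(hits)


def additive_scan(y, genotypes: GenotypeMatrix, K=None, n_axes: int = 3,
                  alpha: float = 0.05, n_perm: Optional[int] = None,
                  seed: int = 0) -> AdditiveScanResult:
    """Run both additive analyses and assemble one result table."""
    if K is None:
        from .kinship import compute_kinship
        K = compute_kinship(genotypes)
    score = structure_adjusted_scan(y, genotypes, K, n_axes=n_axes)
    hem = HemScan().fit(genotypes, y)
    table = pd.DataFrame({
        "snp": genotypes.snp_ids,
        "chromosome": [s.chromosome for s in genotypes.snps],
        "position": [s.position for s in genotypes.snps],
        "effect": score["effect"], "score_p": score["score_p"],
        "hem_effect": hem.effects_,
    })
    thr = None
    if n_perm:
        thr = hem.permutation_threshold(y, n_perm=n_perm, seed=seed)
    return AdditiveScanResult(table=table,
                              bonferroni_p=alpha / genotypes.m,
                              hem_threshold=thr)
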