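"""Exhaustive two-locus epistasis scan and its post-processing.

Every unordered pair of common SNPs is fitted with the four-term model

    Y ~ b0 + b1 A + b2 B + b3 AB + e

with A, B the -1/+1 homozygote dosages, so b3 carries the
allele-by-allele interaction.  Pairs whose smallest two-locus genotype
class is underpopulated are skipped; surviving pairs are pre-filtered on
the OLS interaction p-value, refitted under a kinship-corrected mixed
model, thresholded against an LD-block Bonferroni correction, collapsed
into unique groups of mutually linked pairs, and summarized by per-pair
and joint variance explained.

Because A, B in {-1, +1}, the normal equations of the four-term model
depend on the data only through n, the column sums of A, B and AB, and
the phenotype cross-products — which lets the scan run as a handful of
matrix products over all pairs at once.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, KinshipMatrix, ScanConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def filter_snps(genotypes: GenotypeMatrix,
                maf_min: float = 0.25) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above ``maf_min``."""
    maf = genotypes.maf()
    keep = maf > maf_min
    if not keep.any():
        counts, edges = np.histogram(maf[np.isfinite(maf)],
                                     bins=10, range=(0.0, 0.5))
        logger.error("MAF filter %g left no SNPs; MAF histogram "
                     "(bins %s): %s", maf_min, np.round(edges, 2).tolist(),
                     counts.tolist())
        raise ValueError(f"no SNPs with MAF > {maf_min}")
    return genotypes.select_snps(keep)


# ---------------------------------------------------------------------------
# pair scan
# ---------------------------------------------------------------------------

class EpistasisScan:
    """Exhaustive OLS pre-scan over all unordered SNP pairs.

    Parameters follow the study defaults: ``maf_min=0.25`` (strict),
    ``min_class_count=4``, ``prefilter_p=1e-8``.

    After :meth:`fit`:

    results_ : DataFrame of retained pairs (p_ols <= prefilter_p) with
        coefficients, class counts and per-pair variance explained.
    counts_ : dict reconciling pairs_total = skipped_class +
        skipped_collinear + visited; retained <= visited.
    k_histogram_ : {double-minor class count k: number of visited pairs},
        the input of the small-sample false-positive statistic.
    """

    def __init__(self, maf_min: float = 0.25, min_class_count: int = 4,
                 prefilter_p: float = 1e-8, block_size: int = 512,
                 apply_maf_filter: bool = True):
        self.maf_min = maf_min
        self.min_class_count = min_class_count
        self.prefilter_p = prefilter_p
        self.block_size = block_size
        self.apply_maf_filter = apply_maf_filter

    def fit(self, X: GenotypeMatrix, y) -> "EpistasisScan":
        y = np.asarray(y, dtype=float)
        gm = filter_snps(X, self.maf_min) if self.apply_maf_filter else X
        if (gm.calls == 0).any():
            raise ValueError(
                "the pair scan requires complete genotypes; drop or mask "
                "missing calls at load")
        self.genotypes_ = gm
        n, m = gm.n, gm.m
        if y.size != n:
            raise ValueError("phenotype is misaligned with the panel")
        G = gm.calls.astype(np.float64)
        sA = G.sum(axis=0)
        Sy = float(y.sum())
        SyA = G.T @ y
        yy = float(y @ y)
        sst = yy - Sy ** 2 / n
        dof = n - 4

        total = skipped_class = skipped_collinear = visited = 0
        k_hist: Dict[int, int] = {}
        rows: List[dict] = []

        bs = self.block_size
        for i0 in range(0, m, bs):
            i1 = min(i0 + bs, m)
            Gi = G[:, i0:i1]
            S_blk = Gi.T @ G                     # (bi, m) cross sums
            W_blk = (Gi * y[:, None]).T @ G      # (bi, m) y-weighted sums
            for ii in range(i1 - i0):
                i = i0 + ii
                j = np.arange(i + 1, m)
                if j.size == 0:
                    continue
                total += j.size
                sAB = S_blk[ii, i + 1:]
                sB = sA[i + 1:]
                sAi = sA[i]
                cpp = (n + sAi + sB + sAB) / 4.0
                cpm = (n + sAi - sB - sAB) / 4.0
                cmp_ = (n - sAi + sB - sAB) / 4.0
                cmm = (n - sAi - sB + sAB) / 4.0
                counts4 = np.stack([cmm, cpm, cmp_, cpp])
                cmin = counts4.min(axis=0)
                coll = np.abs(sAB) >= n
                cls = (cmin < self.min_class_count) & ~coll
                keep = ~(coll | cls)
                skipped_collinear += int(coll.sum())
                skipped_class += int(cls.sum())
                if not keep.any():
                    continue
                visited += int(keep.sum())
                jj = j[keep]
                kvals, kcounts = np.unique(cpp[keep].astype(int),
                                           return_counts=True)
                for kv, kc in zip(kvals, kcounts):
                    k_hist[int(kv)] = k_hist.get(int(kv), 0) + int(kc)

                b, p, r2, se3 = _pair_ols_block(
                    n, sAi, sB[keep], sAB[keep], Sy, SyA[i], SyA[jj],
                    W_blk[ii, jj], yy, sst, dof)
                hit = p <= self.prefilter_p
                for t in np.flatnonzero(hit):
                    jt = int(jj[t])
                    rows.append({
                        "snp_a": gm.snps[i].id, "snp_b": gm.snps[jt].id,
                        "idx_a": i, "idx_b": jt,
                        "b0": b[t, 0], "b1": b[t, 1], "b2": b[t, 2],
                        "b3": b[t, 3], "b3_01_coding": 4.0 * b[t, 3],
                        "se_b3": se3[t], "p_ols": p[t],
                        "count_mm": int(cmm[keep][t]),
                        "count_mp": int(cmp_[keep][t]),
                        "count_pm": int(cpm[keep][t]),
                        "count_pp": int(cpp[keep][t]),
                        "r2_pair": r2[t],
                    })

        self.counts_ = {"pairs_total": total, "skipped_class": skipped_class,
                        "skipped_collinear": skipped_collinear,
                        "visited": visited, "retained": len(rows)}
        assert total == skipped_class + skipped_collinear + visited
        cols = ["snp_a", "snp_b", "idx_a", "idx_b", "b0", "b1", "b2", "b3",
                "b3_01_coding", "se_b3", "p_ols", "count_mm", "count_mp",
                "count_pm", "count_pp", "r2_pair"]
        self.results_ = (pd.DataFrame(rows, columns=cols)
                         .sort_values("p_ols", ignore_index=True)
                         if rows else pd.DataFrame(columns=cols))
        self.results_["p_mixed"] = np.nan
        self.k_histogram_ = dict(sorted(k_hist.items()))
        return self


def _pair_ols_block(n, sAi, sB, sAB, Sy, SyAi, SyB, SyAB, yy, sst, dof):
    """Vectorized OLS of the four-term model for one anchor SNP.

    For -1/+1 dosages A^2 = B^2 = (AB)^2 = 1, A*AB = B and B*AB = A, so
    X'X is fully determined by (n, sum A, sum B, sum AB).
    """
    K = sB.size
    XtX = np.empty((K, 4, 4))
    XtX[:, 0, 0] = XtX[:, 1, 1] = XtX[:, 2, 2] = XtX[:, 3, 3] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = XtX[:, 2, 3] = XtX[:, 3, 2] = sAi
    XtX[:, 0, 2] = XtX[:, 2, 0] = XtX[:, 1, 3] = XtX[:, 3, 1] = sB
    XtX[:, 0, 3] = XtX[:, 3, 0] = XtX[:, 1, 2] = XtX[:, 2, 1] = sAB
    Xty = np.empty((K, 4))
    Xty[:, 0] = Sy
    Xty[:, 1] = SyAi
    Xty[:, 2] = SyB
    Xty[:, 3] = SyAB
    b = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    rss = np.maximum(yy - np.einsum("kp,kp->k", b, Xty), 0.0)
    s2 = rss / dof
    inv33 = np.linalg.inv(XtX)[:, 3, 3]
    se3 = np.sqrt(np.maximum(s2 * inv33, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se3 > 0, b[:, 3] / np.where(se3 > 0, se3, 1.0),
                         np.where(b[:, 3] != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    r2 = 1.0 - rss / sst if sst > 0 else np.zeros(K)
    return b, p, r2, se3


def pair_scan(y, genotypes: GenotypeMatrix,
              config: Optional[ScanConfig] = None) -> EpistasisScan:
    """Thin wrapper: run the exhaustive pre-scan under a config."""
    cfg = config or ScanConfig()
    scan = EpistasisScan(maf_min=cfg.maf_min,
                         min_class_count=cfg.min_class_count,
                         prefilter_p=cfg.prefilter_p)
    return scan.fit(genotypes, y)


# ---------------------------------------------------------------------------
# mixed-model refit of survivors
# ---------------------------------------------------------------------------

def mixed_refit(y, survivors: pd.DataFrame, genotypes: GenotypeMatrix,
                K) -> pd.DataFrame:
    """Kinship-corrected refit of each retained pair.

    Per pair the four fixed terms are refitted with a random accession
    effect of covariance G sigma_g^2 (variance ratio by REML on the
    rotated model); ``p_mixed`` is the Wald p-value on b3.  Pairs whose
    refit fails keep ``p_mixed`` missing.
    """
    y = np.asarray(y, dtype=float)
    K = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    out = survivors.copy()
    p_mixed = np.full(len(out), np.nan)
    b3_mixed = np.full(len(out), np.nan)
    for r, row in enumerate(out.itertuples(index=False)):
        A = genotypes.calls[:, int(row.idx_a)].astype(float)
        B = genotypes.calls[:, int(row.idx_b)].astype(float)
        X = np.column_stack([np.ones(y.size), A, B, A * B])
        try:
            beta, se, _ = _emma_gls(yt, U.T @ X, d)
            tstat = beta[3] / se[3]
            # t reference with n - 4 df (small-n Wald, matching the OLS
            # pre-scan's reference under a degenerate kinship)
            p_mixed[r] = 2.0 * stats.t.sf(abs(tstat), y.size - X.shape[1])
            b3_mixed[r] = beta[3]
        except np.linalg.LinAlgError:
            logger.warning("mixed refit failed for pair %s/%s",
                           row.snp_a, row.snp_b)
    out["b3_mixed"] = b3_mixed
    out["p_mixed"] = p_mixed
    return out


def _emma_gls(yt, Xt, d, max_log_lambda: float = 12.0):
    """REML variance ratio + GLS fit on an eigen-rotated mixed model.

    V = sigma_e^2 (lambda K + I); returns (beta, se, lambda)."""
    n, p = Xt.shape

    def neg2(loglam):
        w = np.exp(loglam) * d + 1.0
        Xw = Xt / w[:, None]
        xtwx = Xt.T @ Xw
        beta = np.linalg.solve(xtwx, Xw.T @ yt)
        r = yt - Xt @ beta
        S = float(r @ (r / w))
        s2 = S / (n - p)
        sign, logdet = np.linalg.slogdet(xtwx)
        return (n - p) * np.log(s2) + np.log(w).sum() + logdet

    res = optimize.minimize_scalar(neg2, bounds=(-max_log_lambda,
                                                 max_log_lambda),
                                   method="bounded")
    lam = float(np.exp(res.x))
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    r = yt - Xt @ beta
    s2 = float(r @ (r / w)) / (n - p)
    cov = s2 * np.linalg.inv(xtwx)
    return beta, np.sqrt(np.diag(cov)), lam


# ---------------------------------------------------------------------------
# multiple-testing threshold
# ---------------------------------------------------------------------------

@dataclass
class PairBonferroni:
    n_blocks: float          # genome length / LD-block size
    n_pairs: float           # unordered block pairs, n_blocks choose 2
    threshold: float         # alpha / n_blocks^2 (matches the printed
                             # genome-wide threshold; see notes)
    threshold_pairs: float   # alpha / n_pairs, the unordered-count variant


def pair_bonferroni(config: Optional[ScanConfig] = None) -> PairBonferroni:
    """LD-block Bonferroni arithmetic for the two-locus scan.

    The genome is treated as genome_length / ld_block independent
    blocks; the number of unordered block pairs is reported alongside
    the threshold alpha / n_blocks^2 used for the significance call.
    """
    cfg = config or ScanConfig()
    nb = cfg.genome_length_bp / cfg.ld_block_bp
    if nb <= 0:
        raise ValueError("genome length and block size must be positive")
    n_pairs = nb * (nb - 1) / 2.0
    return PairBonferroni(n_blocks=nb, n_pairs=n_pairs,
                          threshold=cfg.alpha / nb ** 2,
                          threshold_pairs=cfg.alpha / max(n_pairs, 1.0))


# ---------------------------------------------------------------------------
# collapsing linked duplicate pairs
# ---------------------------------------------------------------------------

def _ld_r2(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    a = genotypes.calls[:, i].astype(float)
    b = genotypes.calls[:, j].astype(float)
    ok = (genotypes.calls[:, i] != 0) & (genotypes.calls[:, j] != 0)
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def collapse_linked(significant: pd.DataFrame, genotypes: GenotypeMatrix,
                    link_r2: float = 0.8) -> pd.DataFrame:
    """Merge pairs detected through tightly linked SNPs.

    Two pairs belong to one unique group when their loci match end to
    end with r^2 >= ``link_r2`` (in either orientation); grouping is the
    transitive closure.  The group representative is the member with the
    smallest mixed-model p (OLS p as fallback).
    """
    out = significant.reset_index(drop=True).copy()
    npairs = len(out)
    parent = list(range(npairs))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    idx = out[["idx_a", "idx_b"]].to_numpy(dtype=int)
    for p_ in range(npairs):
        for q in range(p_ + 1, npairs):
            a1, b1 = idx[p_]
            a2, b2 = idx[q]
            direct = (_ld_r2(genotypes, a1, a2) >= link_r2
                      and _ld_r2(genotypes, b1, b2) >= link_r2)
            crossed = (_ld_r2(genotypes, a1, b2) >= link_r2
                       and _ld_r2(genotypes, b1, a2) >= link_r2)
            if direct or crossed:
                union(p_, q)

    roots = [find(p_) for p_ in range(npairs)]
    group_of = {r: g for g, r in enumerate(dict.fromkeys(roots))}
    out["unique_group"] = [f"group{group_of[r] + 1}" for r in roots]
    crit = out["p_mixed"].fillna(out["p_ols"]) if "p_mixed" in out \
        else out["p_ols"]
    out["is_representative"] = False
    for g in out["unique_group"].unique():
        sel = out.index[out["unique_group"] == g]
        out.loc[crit.loc[sel].idxmin(), "is_representative"] = True
    return out


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def _design_for_pairs(genotypes: GenotypeMatrix,
                      pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    cols = [np.ones(genotypes.n)]
    for ia, ib in pairs:
        A = genotypes.calls[:, ia].astype(float)
        B = genotypes.calls[:, ib].astype(float)
        cols.extend([A, B, A * B])
    return np.column_stack(cols)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0


def variance_explained(y, genotypes: GenotypeMatrix,
                       unique_pairs: Sequence[Tuple[int, int]],
                       n_boot: int = 1000, seed: int = 0,
                       ci: float = 0.95) -> Tuple[pd.DataFrame, dict]:
    """Per-pair and joint fraction of phenotypic variance explained.

    Per pair: R^2 of the four-term model.  Joint: R^2 of one model
    containing every unique pair's A, B and AB columns (aliased columns
    are handled by the least-squares projection).  Confidence intervals
    are percentile bootstrap over accessions, seeded.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2

    designs = [_design_for_pairs(genotypes, [pr]) for pr in unique_pairs]
    joint = _design_for_pairs(genotypes, unique_pairs)

    point = [_ols_r2(X, y) for X in designs]
    joint_point = _ols_r2(joint, y)

    boot = np.empty((n_boot, len(designs) + 1))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        yb = y[take]
        for k, X in enumerate(designs):
            boot[b, k] = _ols_r2(X[take], yb)
        boot[b, -1] = _ols_r2(joint[take], yb)

    rows = []
    for k, (ia, ib) in enumerate(unique_pairs):
        lo, hi = np.percentile(boot[:, k], [lo_q, hi_q])
        rows.append({"snp_a": genotypes.snps[ia].id,
                     "snp_b": genotypes.snps[ib].id,
                     "r2_pair": point[k], "r2_lo": lo, "r2_hi": hi})
    jlo, jhi = np.percentile(boot[:, -1], [lo_q, hi_q])
    joint_summary = {"r2_joint": joint_point, "r2_lo": float(jlo),
                     "r2_hi": float(jhi), "n_boot": n_boot}
    return pd.DataFrame(rows), joint_summary


# ---------------------------------------------------------------------------
# local LD candidate window
# ---------------------------------------------------------------------------

def local_ld(leading_snp: str, genotypes: GenotypeMatrix,
             window_bp: float = 1e4, r2_min: float = 0.8) -> pd.DataFrame:
    """SNPs within +-window/2 of the leading SNP with r^2 >= ``r2_min``.

    The leading SNP itself is always listed (r^2 = 1)."""
    j0 = genotypes.snp_index(leading_snp)
    lead = genotypes.snps[j0]
    half = window_bp / 2.0
    rows = []
    for j, s in enumerate(genotypes.snps):
        if s.chromosome != lead.chromosome:
            continue
        if abs(s.position - lead.position) > half:
            continue
        r2 = 1.0 if j == j0 else _ld_r2(genotypes, j0, j)
        if r2 >= r2_min:
            rows.append({"snp": s.id, "chromosome": s.chromosome,
                         "position": s.position, "r2": r2})
    return (pd.DataFrame(rows, columns=["snp", "chromosome", "position", "r2"])
            .sort_values("position", ignore_index=True))
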