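"""Exact small-sample false-positive statistic for epistatic pairs.

Each SNP pair defines a double-recessive pseudo-marker: the binary
indicator of the minor-allele double-homozygote.  Given the phenotype,
the null distribution of the carrier/non-carrier mean difference for a
pseudo-marker with k carriers depends only on k, so the experiment-wise
false-positive probability of an observed pair effect is determined by
the genome-wide distribution {k: M_k} of pseudo-marker carrier counts:

    FPR = 1 - prod_k (1 - p_k)^{M_k},

where p_k is the probability that a random size-k carrier set matches or
exceeds the observed absolute mean difference — computed by exhaustive
enumeration of all C(n, k) subsets when feasible, else by seeded
Monte-Carlo (a permutation-equivalent test).  Independence of the
pseudo-markers is assumed, which is conservative under LD.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional

import numpy as np

from .datatypes import GenotypeMatrix, KinshipMatrix


# ---------------------------------------------------------------------------
# pseudo-markers
# ---------------------------------------------------------------------------

@dataclass
class PseudoMarker:
    """Double-recessive pseudo-marker of a SNP pair."""

    snp_a: str
    snp_b: str
    indicator: np.ndarray  # bool, 1 = minor-allele double-homozygote
    k: int
    n: int

    @property
    def maf_pm(self) -> float:
        return self.k / self.n

    @property
    def testable(self) -> bool:
        return 0 < self.k < self.n


def make_pseudomarker(genotypes: GenotypeMatrix, snp_a: str,
                      snp_b: str) -> PseudoMarker:
    """Indicator of carrying the +1 homozygote at both loci."""
    ja = genotypes.snp_index(snp_a)
    jb = genotypes.snp_index(snp_b)
    ind = (genotypes.calls[:, ja] == 1) & (genotypes.calls[:, jb] == 1)
    return PseudoMarker(snp_a=snp_a, snp_b=snp_b, indicator=ind,
                        k=int(ind.sum()), n=genotypes.n)


def count_distribution(k_values) -> Dict[int, int]:
    """Histogram {carrier count k: number of pseudo-markers M_k}.

    ``k_values`` may be an iterable of per-pair double-minor class counts
    or an already-built mapping (returned unchanged after validation).
    """
    if isinstance(k_values, dict):
        return {int(k): int(v) for k, v in sorted(k_values.items())}
    out: Dict[int, int] = {}
    for k in k_values:
        out[int(k)] = out.get(int(k), 0) + 1
    return dict(sorted(out.items()))


def count_distribution_from_panel(genotypes: GenotypeMatrix,
                                  maf_min: float = 0.25,
                                  min_class_count: int = 4
                                  ) -> Dict[int, int]:
    """Recompute the carrier-count histogram over all pairs passing the
    scan filters, without fitting any models."""
    from .epistasis import filter_snps
    gm = filter_snps(genotypes, maf_min)
    G = gm.calls.astype(np.float64)
    n, m = gm.n, gm.m
    sA = G.sum(axis=0)
    S = G.T @ G
    iu = np.triu_indices(m, k=1)
    sAB = S[iu]
    sa, sb = sA[iu[0]], sA[iu[1]]
    cpp = (n + sa + sb + sAB) / 4.0
    cpm = (n + sa - sb - sAB) / 4.0
    cmp_ = (n - sa + sb - sAB) / 4.0
    cmm = (n - sa - sb + sAB) / 4.0
    cmin = np.minimum(np.minimum(cpp, cpm), np.minimum(cmp_, cmm))
    ok = (cmin >= min_class_count) & (np.abs(sAB) < n)
    ks, Ms = np.unique(cpp[ok].astype(int), return_counts=True)
    return {int(k): int(M) for k, M in zip(ks, Ms)}


# ---------------------------------------------------------------------------
# null tail probability at carrier count k
# ---------------------------------------------------------------------------

def marker_null_tail(y, k: int, observed_effect: float,
                     cap: int = 200_000, mc_draws: int = 100_000,
                     seed: int = 0) -> tuple[float, str]:
    """P(|carrier mean - non-carrier mean| >= |observed|) over random
    carrier sets of size k.

    Exhaustive over all C(n, k) subsets when that count is within
    ``cap``; otherwise seeded Monte-Carlo with an add-one correction.
    Returns (p_k, method).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not (0 < k < n):
        raise ValueError(f"carrier count k = {k} must satisfy 0 < k < n = {n}")
    target = abs(observed_effect)
    if target == 0.0:
        return 1.0, "exact"
    total = y.sum()
    n_subsets = math.comb(n, k)
    # |mean_S - mean_rest| from the subset sum alone
    scale = 1.0 / k + 1.0 / (n - k)

    if n_subsets <= cap:
        idx = np.fromiter((i for c in combinations(range(n), k) for i in c),
                          dtype=np.intp, count=n_subsets * k).reshape(-1, k)
        sums = y[idx].sum(axis=1)
        diffs = np.abs(sums * scale - total / (n - k))
        hits = int((diffs >= target - 1e-12).sum())
        return hits / n_subsets, "exact"

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((mc_draws, n)), axis=1)[:, :k]
    sums = y[order].sum(axis=1)
    diffs = np.abs(sums * scale - total / (n - k))
    hits = int((diffs >= target - 1e-12).sum())
    return (hits + 1) / (mc_draws + 1), "monte-carlo"


# ---------------------------------------------------------------------------
# genome-wide aggregation
# ---------------------------------------------------------------------------

@dataclass
class ExactFprResult:
    snp_a: str
    snp_b: str
    k: int
    observed_effect: float            # carrier/non-carrier mean diff (mm)
    count_distribution: Dict[int, int]
    tail_p: Dict[int, float]
    method: Dict[int, str]
    fpr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fpr <= 1.0):
            raise ValueError("fpr must lie in [0, 1]")


def structure_adjust(y, K, n_axes: int = 3) -> np.ndarray:
    """Residualize a phenotype on the intercept plus the top ``n_axes``
    kinship eigenvectors (the additive scan's structure adjustment)."""
    y = np.asarray(y, dtype=float)
    K = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    w, U = np.linalg.eigh(K)
    Q = np.column_stack([np.ones(y.size), U[:, ::-1][:, :n_axes]])
    return y - Q @ np.linalg.lstsq(Q, y, rcond=None)[0]


def aggregate_fpr(tail_p: Dict[int, float],
                  counts: Dict[int, int]) -> float:
    """1 - prod_k (1 - p_k)^{M_k} under pseudo-marker independence."""
    log_keep = 0.0
    for k, M in counts.items():
        p = tail_p[k]
        if p >= 1.0:
            return 1.0
        log_keep += M * math.log1p(-p)
    return float(min(max(-math.expm1(log_keep), 0.0), 1.0))


def genome_wide_fpr(y, pseudo: PseudoMarker, counts: Dict[int, int],
                    K=None, n_axes: int = 3, cap: int = 200_000,
                    mc_draws: int = 100_000, seed: int = 0
                    ) -> ExactFprResult:
    """Experiment-wise false-positive probability of an observed pair.

    The observed effect is the carrier/non-carrier mean difference on
    the structure-adjusted phenotype (adjustment skipped when no kinship
    is given); p_k is evaluated per distinct carrier count in ``counts``
    and aggregated under the independence assumption.
    """
    if not pseudo.testable:
        raise ValueError(
            f"pseudo-marker {pseudo.snp_a}/{pseudo.snp_b} with k = "
            f"{pseudo.k} of n = {pseudo.n} is untestable")
    y = np.asarray(y, dtype=float)
    if K is not None:
        y = structure_adjust(y, K, n_axes=n_axes)
    ind = pseudo.indicator.astype(bool)
    observed = float(y[ind].mean() - y[~ind].mean())

    tail_p: Dict[int, float] = {}
    method: Dict[int, str] = {}
    for j, k in enumerate(sorted(counts)):
        p, how = marker_null_tail(y, int(k), observed, cap=cap,
                                  mc_draws=mc_draws, seed=seed + j)
        tail_p[int(k)] = p
        method[int(k)] = how
    fpr = aggregate_fpr(tail_p, counts)
    return ExactFprResult(snp_a=pseudo.snp_a, snp_b=pseudo.snp_b,
                          k=pseudo.k, observed_effect=observed,
                          count_distribution=dict(counts), tail_p=tail_p,
                          method=method, fpr=fpr)
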