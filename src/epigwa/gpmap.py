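"""Two-locus genotype-phenotype maps and additive/epistatic variance
decomposition.

A two-locus G-P map is the 2x2 table of mean phenotypes for the four
homozygous genotype classes (x_A, x_B) in {-1, +1}^2, together with the
observed class frequencies.  Its genetic variance decomposes into the
variance of the best linear predictor in (x_A, x_B) under those
frequencies — the marginal additive part v_a — and the remainder v_aa,
the additive-by-additive epistatic part.  "Epistatic cancellation" is the
case v_a = 0 with v_g > 0: the class means differ but the loci have no
marginal (average) effects at the observed allele frequencies, so the
architecture is invisible to any additive scan.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_LEVELS = (-1, 1)


@dataclass
class GPMap:
    """Estimated two-locus map: class means, counts and frequencies.

    Arrays are indexed ``[i_a, i_b]`` with index 0 for the -1 (major)
    homozygote and index 1 for the +1 (minor) homozygote.  Empty classes
    carry NaN means and zero frequency.
    """

    means: np.ndarray   # (2, 2), mm; NaN where the class is empty
    counts: np.ndarray  # (2, 2) accession counts
    freqs: np.ndarray   # (2, 2), counts / n

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(2, 2)
        self.counts = np.asarray(self.counts, dtype=float).reshape(2, 2)
        self.freqs = np.asarray(self.freqs, dtype=float).reshape(2, 2)
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("class frequencies must sum to 1")

    @property
    def n(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def n_classes(self) -> int:
        return int((self.freqs > 0).sum())

    @property
    def empty_classes(self) -> list[tuple[int, int]]:
        return [(a, b) for a in _LEVELS for b in _LEVELS
                if self.freqs[(a + 1) // 2, (b + 1) // 2] == 0]


def independent_freqs(q_a: float, q_b: float) -> np.ndarray:
    """Joint class frequencies for independent loci with minor-allele
    (i.e. +1 homozygote) frequencies ``q_a`` and ``q_b``."""
    fa = np.array([1.0 - q_a, q_a])
    fb = np.array([1.0 - q_b, q_b])
    return np.outer(fa, fb)


def estimate_gpmap(y, a_calls, b_calls) -> GPMap:
    """Class means of ``y`` over the four two-locus genotype classes.

    Accessions with a missing call at either locus are excluded.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a_calls)
    b = np.asarray(b_calls)
    if not (len(y) == len(a) == len(b)):
        raise ValueError(
            f"phenotype (n={len(y)}) and genotype vectors "
            f"(n={len(a)}, n={len(b)}) are misaligned")
    ok = (a != 0) & (b != 0) & np.isfinite(y)
    a, b, y = a[ok], b[ok], y[ok]
    means = np.full((2, 2), np.nan)
    counts = np.zeros((2, 2))
    for ia, va in enumerate(_LEVELS):
        for ib, vb in enumerate(_LEVELS):
            sel = (a == va) & (b == vb)
            counts[ia, ib] = sel.sum()
            if sel.any():
                means[ia, ib] = y[sel].mean()
    n = counts.sum()
    if n == 0:
        raise ValueError("no complete observations for this pair")
    return GPMap(means=means, counts=counts, freqs=counts / n)


@dataclass
class GPMapDecomposition:
    """Additive/epistatic split of a two-locus map's genetic variance.

    ``v_a`` is the variance of the weighted least-squares projection of
    the class means onto {1, x_A, x_B}; ``v_aa = v_g - v_a``.  The
    cancellation index v_a / v_g is 0 under complete epistatic
    cancellation and 1 for a purely additive map.
    """

    v_g: float
    v_a: Optional[float]
    v_aa: Optional[float]
    cancellation_index: Optional[float]
    n_classes: int

    @property
    def defined(self) -> bool:
        return self.v_a is not None


def decompose_map(means, freqs) -> GPMapDecomposition:
    """Decompose a 2x2 map at the given class frequencies.

    Population moments are taken under ``freqs``; only non-empty classes
    enter.  With fewer than 3 non-empty classes the additive projection
    is undetermined and ``v_a`` is flagged undefined.
    """
    means = np.asarray(means, dtype=float).reshape(2, 2)
    freqs = np.asarray(freqs, dtype=float).reshape(2, 2)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("class frequencies must sum to 1")
    mask = freqs > 0
    n_classes = int(mask.sum())
    if n_classes < 2:
        raise ValueError("v_g requires at least 2 non-empty classes")
    if np.isnan(means[mask]).any():
        raise ValueError("non-empty class with undefined mean")

    xa = np.array([[-1.0, -1.0], [1.0, 1.0]])
    xb = np.array([[-1.0, 1.0], [-1.0, 1.0]])
    w = freqs[mask]
    g = means[mask]
    mu = float(w @ g)
    v_g = float(w @ (g - mu) ** 2)

    if n_classes < 3:
        return GPMapDecomposition(v_g=v_g, v_a=None, v_aa=None,
                                  cancellation_index=None,
                                  n_classes=n_classes)

    # weighted least squares of class means on {1, x_A, x_B}
    X = np.column_stack([np.ones(n_classes), xa[mask], xb[mask]])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], g * sw, rcond=None)
    fitted = X @ beta
    v_a = float(w @ (fitted - mu) ** 2)
    # numerical guard: the identity v_g = v_a + v_aa holds exactly
    v_a = min(max(v_a, 0.0), v_g) if v_g > 0 else max(v_a, 0.0)
    v_aa = v_g - v_a
    ci = v_a / v_g if v_g > 0 else None
    return GPMapDecomposition(v_g=v_g, v_a=v_a, v_aa=v_aa,
                              cancellation_index=ci, n_classes=n_classes)


def decompose_variance(gp: GPMap) -> GPMapDecomposition:
    """Decompose an estimated map at its observed joint class frequencies."""
    return decompose_map(gp.means, gp.freqs)


def cancellation_report(y, genotypes, pairs: Sequence[tuple]) -> pd.DataFrame:
    """Per-pair G-P map and variance decomposition table.

    Parameters
    ----------
    y : accession phenotype vector aligned to ``genotypes``.
    genotypes : :class:`~epigwa.datatypes.GenotypeMatrix`.
    pairs : sequence of ``(snp_id_a, snp_id_b)`` (the unique pairs from
        the epistasis scan).

    Each row reports the four class means/counts, v_g, v_a, v_aa, the
    cancellation index, and the rank of the minor-allele
    double-homozygote mean among the four classes (1 = longest root).
    """
    rows = []
    for id_a, id_b in pairs:
        ja = genotypes.snp_index(id_a)
        jb = genotypes.snp_index(id_b)
        gp = estimate_gpmap(y, genotypes.calls[:, ja], genotypes.calls[:, jb])
        dec = decompose_variance(gp)
        order = np.argsort(-gp.means, axis=None)  # NaN sorts last
        rank_pp = int(np.where(order == 3)[0][0]) + 1  # flat index 3 = (+1,+1)
        rows.append({
            "snp_a": id_a, "snp_b": id_b,
            "mean_mm": gp.means[0, 0], "mean_mp": gp.means[0, 1],
            "mean_pm": gp.means[1, 0], "mean_pp": gp.means[1, 1],
            "count_mm": gp.counts[0, 0], "count_mp": gp.counts[0, 1],
            "count_pm": gp.counts[1, 0], "count_pp": gp.counts[1, 1],
            "v_g": dec.v_g, "v_a": dec.v_a, "v_aa": dec.v_aa,
            "cancellation_index": dec.cancellation_index,
            "minor_double_homozygote_rank": rank_pp,
        })
    return pd.DataFrame(rows)
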