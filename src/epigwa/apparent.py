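"""Apparent-epistasis risk via high-order LD bootstrap.

A significant SNP pair may tag a single unobserved causal variant: any
variant in high LD (r^2) with the pair's double-recessive pseudo-marker
can masquerade as epistasis.  Against a large re-sequenced reference
panel, subsamples of the GWA population's size are drawn repeatedly with
the pseudo-marker's carrier frequency preserved, and the squared
correlation between the pseudo-marker and every reference variant is
profiled: the grand mean r^2, the per-replicate maximum r^2, and the
probability of r^2_max exceeding a tagging threshold (0.8) estimated
from a Gaussian fit to the replicate-level maxima.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix


def sample_preserving_frequency(panel_indicator: np.ndarray, maf_pm: float,
                                n_sample: int = 93,
                                rng: Optional[np.random.Generator] = None,
                                seed: int = 0) -> np.ndarray:
    """Subsample panel accessions keeping the pseudo-marker frequency.

    Draws exactly round(maf_pm * n_sample) carriers and the rest
    non-carriers, uniformly within each stratum.  Returns accession
    indices into the panel.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ind = np.asarray(panel_indicator).astype(bool)
    carriers = np.flatnonzero(ind)
    others = np.flatnonzero(~ind)
    n_carr = int(round(maf_pm * n_sample))
    if n_carr > carriers.size:
        raise ValueError(
            f"reference panel holds {carriers.size} pseudo-marker carriers "
            f"but the frequency-preserving sample needs {n_carr}")
    if n_sample - n_carr > others.size:
        raise ValueError("not enough non-carriers in the reference panel")
    take = np.concatenate([
        rng.choice(carriers, size=n_carr, replace=False),
        rng.choice(others, size=n_sample - n_carr, replace=False)])
    return np.sort(take)


@dataclass
class LdRiskProfile:
    """Bootstrap summary of high-order LD between a pseudo-marker and a
    reference panel."""

    snp_a: str
    snp_b: str
    r2_mean: float               # grand mean over variants and replicates
    r2_mean_sd: float            # spread of per-replicate means
    r2_max: float                # mean of per-replicate maxima
    r2_max_sd: float             # spread of per-replicate maxima
    p_exceed: float              # Gaussian tail P(r2_max > threshold)
    p_exceed_empirical: float    # fraction of replicates exceeding
    reps: int
    n_sample: int
    threshold: float
    excluded: List[str] = field(default_factory=list)
    n_skipped_monomorphic: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_mean <= self.r2_max + 1e-12 <= 1.0 + 1e-12):
            raise ValueError("expected 0 <= r2_mean <= mean r2_max <= 1")
        if not (0.0 <= self.p_exceed <= 1.0):
            raise ValueError("p_exceed must lie in [0, 1]")


def gaussian_tail_risk(mean_max: float, spread_max: float,
                       threshold: float = 0.8) -> float:
    """Upper-tail probability of r^2_max beyond the threshold under a
    Gaussian with the replicate-level mean and spread.

    A zero spread degenerates to 0 or 1 by the sign of
    (threshold - mean); an exact tie gives 0.5.
    """
    if spread_max < 0:
        raise ValueError("spread_max must be >= 0")
    if spread_max == 0.0:
        if mean_max == threshold:
            return 0.5
        return 0.0 if mean_max < threshold else 1.0
    return float(stats.norm.sf((threshold - mean_max) / spread_max))


def highorder_ld_profile(panel: GenotypeMatrix, pseudo_indicator: np.ndarray,
                         maf_pm: float, snp_a: str = "", snp_b: str = "",
                         reps: int = 50, n_sample: int = 93,
                         threshold: float = 0.8,
                         exclude_ids: Sequence[str] = (),
                         exclude_window_bp: float = 1.0,
                         seed: int = 0) -> LdRiskProfile:
    """Frequency-preserving bootstrap of the r^2 profile.

    Parameters
    ----------
    panel : reference haplotype panel (e.g. 728 re-sequenced accessions).
    pseudo_indicator : binary carrier vector over the panel accessions.
    maf_pm : the pseudo-marker's carrier frequency in the GWA panel,
        preserved in every subsample.
    exclude_ids : variant ids to leave out of the scan (the pair's own
        loci and, optionally, all genotyped GWA markers); positions
        within ``exclude_window_bp`` of the pair's loci are also dropped.

    Per replicate, the squared Pearson correlation between the
    pseudo-marker indicator and every variant dosage is computed over
    the sampled accessions; variants monomorphic within a sample are
    skipped for that replicate and counted.
    """
    rng = np.random.default_rng(seed)
    ind = np.asarray(pseudo_indicator).astype(float)

    excluded = set(exclude_ids)
    for locus in (snp_a, snp_b):
        if not locus:
            continue
        try:
            chrom, pos = locus.rsplit("_", 1)
            pos = int(pos)
        except ValueError:
            continue
        for s in panel.snps:
            if (s.chromosome == chrom
                    and abs(s.position - pos) <= exclude_window_bp):
                excluded.add(s.id)
    keep = np.array([s.id not in excluded for s in panel.snps])
    D_all = panel.calls[:, keep].astype(float)

    rep_mean = np.empty(reps)
    rep_max = np.empty(reps)
    n_skipped = 0
    for b in range(reps):
        take = sample_preserving_frequency(ind, maf_pm, n_sample, rng=rng)
        x = ind[take]
        D = D_all[take, :]
        xc = x - x.mean()
        xn = np.sqrt((xc ** 2).sum())
        Dc = D - D.mean(axis=0)
        dn = np.sqrt((Dc ** 2).sum(axis=0))
        poly = dn > 0
        n_skipped += int((~poly).sum())
        if xn == 0 or not poly.any():
            rep_mean[b] = rep_max[b] = 0.0
            continue
        r = (xc @ Dc[:, poly]) / (xn * dn[poly])
        r2 = r ** 2
        rep_mean[b] = r2.mean()
        rep_max[b] = r2.max()

    mean_max = float(rep_max.mean())
    sd_max = float(rep_max.std(ddof=1)) if reps > 1 else 0.0
    return LdRiskProfile(
        snp_a=snp_a, snp_b=snp_b,
        r2_mean=float(rep_mean.mean()),
        r2_mean_sd=float(rep_mean.std(ddof=1)) if reps > 1 else 0.0,
        r2_max=mean_max, r2_max_sd=sd_max,
        p_exceed=gaussian_tail_risk(mean_max, sd_max, threshold),
        p_exceed_empirical=float((rep_max > threshold).mean()),
        reps=reps, n_sample=n_sample, threshold=threshold,
        excluded=sorted(excluded), n_skipped_monomorphic=n_skipped)
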