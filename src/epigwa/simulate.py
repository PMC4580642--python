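"""Synthetic data generators emulating the study system.

The generators produce (i) a structured inbred biallelic panel
(Balding-Nichols divergence model with haploid-equivalent sampling, so
every call is homozygous), (ii) two-locus epistatic genotype-phenotype
maps — including maps constructed to cancel the additive genetic
variance exactly at chosen allele frequencies, (iii) seedling-level
measurements with the plate design of the study (sets x replicates, a
shared control accession, occasional short hypocotyls), and (iv) a large
reference haplotype panel, optionally carrying one variant in high LD
with a given two-locus pseudo-marker.

Defaults encode the study conditions: 93 accessions, 4 sets of 23
accessions plus the control replicated 3 times with 70 seedlings per
accession and replicate, and an accession-level broad-sense heritability
of 0.25.  All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SnpInfo
from .gpmap import decompose_map, independent_freqs

_CHROMS = ("1", "2", "3", "4", "5")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Balding-Nichols panel specification.

    ``fst`` is the divergence of each subpopulation from the common
    ancestral pool; ``ancestral_maf_range`` bounds the uniform ancestral
    allele-frequency draw per SNP.
    """

    n_accessions: int = 93
    n_snps: int = 1000
    n_subpops: int = 3
    fst: float = 0.3
    ancestral_maf_range: Tuple[float, float] = (0.05, 0.5)
    pos_spacing_bp: float = 5e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"fst must lie in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi < 0.5 or (0.0 < lo <= hi <= 0.5)):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")


@dataclass
class GPMapSpec:
    """A 2x2 genotype-phenotype map (mm) with its target minor-allele
    frequencies; ``means[i_a, i_b]`` with index 0 for -1, 1 for +1."""

    means: np.ndarray
    freq_minor_a: float
    freq_minor_b: float
    label: str = ""

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(2, 2)
        if not np.isfinite(self.means).all():
            raise ValueError("all four class means must be finite")
        for q in (self.freq_minor_a, self.freq_minor_b):
            if not (0.0 < q < 1.0):
                raise ValueError("map frequencies must lie in (0, 1)")

    def genetic_variance(self) -> float:
        """Population genetic variance under independent loci at the
        map's frequencies."""
        dec = decompose_map(self.means,
                            independent_freqs(self.freq_minor_a,
                                              self.freq_minor_b))
        return dec.v_g


@dataclass
class TruthRecord:
    """Ground truth for one planted epistatic pair."""

    snp_a: int                 # column index of locus A in the panel
    snp_b: int
    gpmap: GPMapSpec
    residual_sd: float
    realized_r2: float         # realized per-pair variance explained
    sigma2_a: float            # marginal additive variance of the map
    sigma2_aa: float           # epistatic variance of the map
    sigma2_e: float            # residual_sd ** 2

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

def _snp_metadata(n_snps: int, spacing: float) -> list[SnpInfo]:
    """Contiguous chromosome blocks with evenly spaced positions."""
    snps = []
    per_chrom = -(-n_snps // len(_CHROMS))
    for j in range(n_snps):
        chrom = _CHROMS[j // per_chrom]
        pos = int((j % per_chrom + 1) * spacing)
        snps.append(SnpInfo(id=SnpInfo.canonical_id(chrom, pos),
                            chromosome=chrom, position=pos, maf=0.0))
    return snps


def _recode_minor(calls: np.ndarray, snps: list[SnpInfo]) -> None:
    """Flip columns in place so +1 is the panel-minor homozygote.

    A tie at frequency 0.5 keeps the current orientation (lower column
    index convention for synthetic data)."""
    freq = (calls == 1).mean(axis=0)
    for j in np.flatnonzero(freq > 0.5):
        calls[:, j] = -calls[:, j]
    for j, s in enumerate(snps):
        s.maf = float(min(freq[j], 1.0 - freq[j]))


def simulate_panel(spec: PopulationSpec) -> Tuple[GenotypeMatrix, np.ndarray]:
    """Generate a structured inbred panel.

    Each SNP draws an ancestral frequency p ~ U(ancestral_maf_range);
    each subpopulation draws its own frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F); each accession (haploid-equivalent,
    fully inbred) carries the +1 homozygote with its subpopulation's
    frequency.  Returns the panel plus the subpopulation label array.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, k = spec.n_accessions, spec.n_snps, spec.n_subpops
    lo, hi = spec.ancestral_maf_range
    p = rng.uniform(lo, hi, size=m)
    F = spec.fst
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    subpop_freq = rng.beta(a[None, :], b[None, :], size=(k, m))
    labels = np.arange(n) % k
    u = rng.random((n, m))
    calls = np.where(u < subpop_freq[labels, :], 1, -1).astype(np.int8)
    snps = _snp_metadata(m, spec.pos_spacing_bp)
    _recode_minor(calls, snps)
    ids = [f"acc{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(ids, snps, calls, validate=False), labels


# ---------------------------------------------------------------------------
# cancellation maps
# ---------------------------------------------------------------------------

def make_cancellation_map(baseline: float, mixed_deficit: float, q: float,
                          label: str = "cancellation") -> GPMapSpec:
    """Construct a map whose marginal additive effects vanish at shared
    minor-allele frequency ``q`` under independent loci.

    The class means are (baseline, baseline-d, baseline-d,
    baseline + d(1-2q)/q) for (-1,-1), (-1,+1), (+1,-1), (+1,+1): the
    double-minor homozygote is boosted exactly enough that the
    frequency-weighted allele-substitution effect at each locus is zero,
    so cov(g, x_A) = cov(g, x_B) = 0 and the whole genetic variance is
    additive-by-additive.
    """
    if mixed_deficit <= 0:
        raise ValueError("mixed_deficit must be > 0")
    if not (0.0 < q <= 0.5):
        raise ValueError(f"q must lie in (0, 0.5], got {q}")
    d = mixed_deficit
    boost = d * (1.0 - 2.0 * q) / q
    means = np.array([[baseline, baseline - d],
                      [baseline - d, baseline + boost]])
    return GPMapSpec(means=means, freq_minor_a=q, freq_minor_b=q, label=label)


def residual_sd_for_r2(gpmap: GPMapSpec, target_r2: float) -> float:
    """Residual sd such that the pair explains ``target_r2`` of the
    phenotypic variance in expectation (independent loci at the map's
    frequencies)."""
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError("target_r2 must lie in (0, 1]")
    v_g = gpmap.genetic_variance()
    return float(np.sqrt(v_g * (1.0 - target_r2) / target_r2))


# ---------------------------------------------------------------------------
# planted pairs
# ---------------------------------------------------------------------------

def _class_r2(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Realized variance explained by the four class means."""
    fitted = np.empty_like(y)
    for va in (-1, 1):
        for vb in (-1, 1):
            sel = (a == va) & (b == vb)
            if sel.any():
                fitted[sel] = y[sel].mean()
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(((y - fitted) ** 2).sum())
    return 1.0 - ssr / sst if sst > 0 else 0.0


def plant_epistatic_pair(genotypes: GenotypeMatrix, gpmap: GPMapSpec,
                         residual_sd: float, seed: int = 0,
                         pair: Optional[Tuple[int, int]] = None,
                         freq_tol: float = 0.05,
                         synthesize: bool = False
                         ) -> Tuple[GenotypeMatrix, np.ndarray, TruthRecord]:
    """Generate accession phenotypes from a two-locus map.

    Each accession's expected value is the map mean for its two-locus
    genotype; independent Gaussian noise with sd ``residual_sd`` is
    added.  The pair is either given, found among panel SNPs whose MAFs
    match the map frequencies within ``freq_tol``, or — with
    ``synthesize=True`` — appended to the panel as two independent loci
    drawn at exactly the target frequencies.

    Returns the (possibly extended) panel, the phenotype vector, and the
    ground-truth record.
    """
    rng = np.random.default_rng(seed)
    gm = genotypes
    if pair is None and not synthesize:
        maf = gm.maf()
        dev_a = np.abs(maf - gpmap.freq_minor_a)
        dev_b = np.abs(maf - gpmap.freq_minor_b)
        ja = int(np.argmin(dev_a))
        dev_b2 = dev_b.copy()
        dev_b2[ja] = np.inf
        jb = int(np.argmin(dev_b2))
        if dev_a[ja] > freq_tol or dev_b[jb] > freq_tol:
            raise ValueError(
                f"no SNP pair within {freq_tol} of target frequencies "
                f"({gpmap.freq_minor_a}, {gpmap.freq_minor_b}); closest "
                f"panel MAFs: {maf[ja]:.3f}, {maf[jb]:.3f} "
                f"(use synthesize=True)")
        pair = (ja, jb)
    elif pair is None:
        # append two independent loci holding the target frequencies
        # exactly (round(q n) minor homozygotes placed at random), so the
        # planted pair always carries the architecture it was asked for
        n = gm.n
        cols = []
        for q in (gpmap.freq_minor_a, gpmap.freq_minor_b):
            n_minor = min(max(int(round(q * n)), 1), n - 1)
            col = np.full(n, -1, dtype=np.int8)
            col[rng.choice(n, size=n_minor, replace=False)] = 1
            cols.append(col)
        max_pos = max(s.position for s in gm.snps) if gm.m else 0
        new_snps = []
        for chrom, col in zip(("2", "4"), cols):
            pos = int(max_pos + 1e6 + len(new_snps))
            new_snps.append(SnpInfo(
                id=SnpInfo.canonical_id(chrom, pos), chromosome=chrom,
                position=pos, maf=float(min((col == 1).mean(),
                                            (col == -1).mean()))))
        calls = np.concatenate([gm.calls, np.stack(cols, axis=1)], axis=1)
        gm = GenotypeMatrix(gm.accession_ids, list(gm.snps) + new_snps,
                            calls, validate=False)
        pair = (gm.m - 2, gm.m - 1)

    ja, jb = pair
    a = gm.calls[:, ja].astype(int)
    b = gm.calls[:, jb].astype(int)
    expected = gpmap.means[(a + 1) // 2, (b + 1) // 2]
    y = expected + rng.normal(0.0, residual_sd, size=gm.n)

    dec = decompose_map(gpmap.means,
                        independent_freqs(gpmap.freq_minor_a,
                                          gpmap.freq_minor_b))
    truth = TruthRecord(snp_a=ja, snp_b=jb, gpmap=gpmap,
                        residual_sd=residual_sd,
                        realized_r2=_class_r2(y, a, b),
                        sigma2_a=dec.v_a, sigma2_aa=dec.v_aa,
                        sigma2_e=residual_sd ** 2)
    return gm, y, truth


# ---------------------------------------------------------------------------
# seedlings
# ---------------------------------------------------------------------------

def simulate_accession_means(n: int = 93, grand_mean: float = 12.0,
                             sd: float = 1.0, control_id: str = "Col-0",
                             seed: int = 0) -> pd.Series:
    """Accession-level mean root lengths (mm), control included.

    The draw is standardized so the panel's realized dispersion equals
    ``sd`` exactly — the accession panel is a fixed set of lines whose
    between-line variance is a property of the panel, not a sampling
    fluctuation.
    """
    rng = np.random.default_rng(seed)
    ids = [control_id] + [f"acc{i + 1:03d}" for i in range(n - 1)]
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std() * sd + grand_mean
    return pd.Series(x, index=ids, name="mean_root_length")


def simulate_seedlings(accession_means: pd.Series, control_id: str = "Col-0",
                       n_sets: int = 4, n_replicates: int = 3,
                       n_per_replicate: int = 70,
                       set_shift_sd: float = 0.5,
                       replicate_shift_sd: float = 0.3,
                       seedling_sd: float = 1.732,
                       short_hypocotyl_rate: float = 0.0016,
                       hypocotyl_mean: float = 8.0,
                       hypocotyl_sd: float = 1.0,
                       seed: int = 0) -> pd.DataFrame:
    """Seedling table under the plate design.

    Non-control accessions are split across ``n_sets`` sets; the control
    accession is grown in every set.  Each record is
    accession mean + set shift + replicate-within-set shift + noise.
    A fraction ``short_hypocotyl_rate`` of seedlings receive a hypocotyl
    below 5 mm (delayed germination) to exercise the downstream filter.
    Defaults mirror the study design: 4 sets of 23 accessions plus the
    control, replicated 3 times, 70 seedlings per accession and
    replicate, within-accession noise sd chosen so the accession-level
    broad-sense heritability is 0.25 at accession-mean sd 1.
    """
    if control_id not in accession_means.index:
        raise ValueError(
            f"control accession {control_id!r} missing from the design; "
            f"it must be grown in every set")
    rng = np.random.default_rng(seed)
    others = [a for a in accession_means.index if a != control_id]
    set_of = {a: (i % n_sets) + 1 for i, a in enumerate(others)}

    set_shift = rng.normal(0.0, set_shift_sd, size=n_sets)
    rep_shift = rng.normal(0.0, replicate_shift_sd,
                           size=(n_sets, n_replicates))

    rows = []
    for s in range(1, n_sets + 1):
        members = [a for a in others if set_of[a] == s] + [control_id]
        for r in range(1, n_replicates + 1):
            shift = set_shift[s - 1] + rep_shift[s - 1, r - 1]
            for acc in members:
                mu = accession_means[acc] + shift
                vals = mu + rng.normal(0.0, seedling_sd, n_per_replicate)
                short = rng.random(n_per_replicate) < short_hypocotyl_rate
                hyp = np.maximum(
                    rng.normal(hypocotyl_mean, hypocotyl_sd, n_per_replicate),
                    5.0)
                hyp[short] = rng.uniform(2.0, 5.0 - 1e-9, short.sum())
                for v, h, sh in zip(vals, hyp, short):
                    rows.append((acc, s, r, max(float(v), 0.0), float(h),
                                 acc == control_id,
                                 "short_hypocotyl" if sh else ""))
    return pd.DataFrame(rows, columns=["accession_id", "set_id",
                                       "replicate_id", "root_length",
                                       "hypocotyl_length", "is_control",
                                       "qc_flags"])


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_reference_panel(n_accessions: int = 728, n_variants: int = 10000,
                             pseudo: Optional[np.ndarray] = None,
                             planted_r2: Optional[float] = None,
                             maf_range: Tuple[float, float] = (0.02, 0.5),
                             seed: int = 0
                             ) -> Tuple[GenotypeMatrix, Optional[int]]:
    """Large haplotype reference panel with independent variants.

    Variants are generated independently of any pseudo-marker.  If
    ``planted_r2`` is given (with a binary ``pseudo`` carrier vector over
    the panel accessions), one extra variant is planted whose sample r2
    with the pseudo-marker lies within +-0.05 of the target; its column
    index is returned (else None).
    """
    rng = np.random.default_rng(seed)
    n, m = n_accessions, n_variants
    freq = rng.uniform(*maf_range, size=m)
    calls = np.where(rng.random((n, m)) < freq[None, :], 1, -1).astype(np.int8)
    snps = _snp_metadata(m, 1e4)

    planted_idx: Optional[int] = None
    if planted_r2 is not None:
        if pseudo is None:
            raise ValueError("planted_r2 requires a pseudo-marker vector")
        if not (0.0 < planted_r2 <= 1.0):
            raise ValueError("planted_r2 must lie in (0, 1]")
        pseudo = np.asarray(pseudo).astype(int)
        if pseudo.shape != (n,):
            raise ValueError("pseudo must be a binary vector over the panel")
        k = int(pseudo.sum())
        if k == 0 or k == n:
            raise ValueError(
                f"planted_r2 infeasible: pseudo-marker carrier count {k} "
                f"of {n} admits no correlated variant")
        planted = _plant_correlated_variant(pseudo, planted_r2, rng)
        col = np.where(planted == 1, 1, -1).astype(np.int8)
        calls = np.concatenate([calls, col[:, None]], axis=1)
        pos = int(snps[-1].position + 1e6)
        snps = snps + [SnpInfo(id=SnpInfo.canonical_id("5", pos),
                               chromosome="5", position=pos, maf=0.0)]
        planted_idx = m

    _recode_minor(calls, snps)
    ids = [f"ref{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(ids, snps, calls, validate=False), planted_idx


def _plant_correlated_variant(pseudo: np.ndarray, target_r2: float,
                              rng: np.random.Generator,
                              tol: float = 0.05,
                              max_iter: int = 100000) -> np.ndarray:
    """Binary variant with sample r2 to ``pseudo`` within +-tol of target.

    Starts from an exact copy (r2 = 1) and flips random entries until the
    squared correlation enters the band; flips that overshoot are
    reverted."""
    v = pseudo.copy()
    n = v.size

    def r2(x):
        if x.std() == 0 or pseudo.std() == 0:
            return 0.0
        return float(np.corrcoef(x, pseudo)[0, 1] ** 2)

    lo, hi = target_r2 - tol, target_r2 + tol
    cur = r2(v)
    for _ in range(max_iter):
        if lo <= cur <= hi:
            return v
        i = int(rng.integers(n))
        old = v[i]
        v[i] = 1 - old
        new = r2(v)
        # greedy single-entry flips from the exact copy (r2 = 1): keep a
        # flip only if it moves r2 strictly toward the target
        if abs(new - target_r2) < abs(cur - target_r2):
            cur = new
        else:
            v[i] = old
    raise ValueError(
        f"could not reach r2 = {target_r2} +- {tol} with carrier count "
        f"{int(pseudo.sum())} of {n}")
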