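"""Shared domain types for the epistatic GWA pipeline.

Genotypes are homozygous biallelic calls from a fully inbred panel, coded
-1 for the major-allele homozygote and +1 for the minor-allele homozygote;
0 is the missing sentinel (the panel contains no heterozygotes, so 0 is
never a valid call).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

#: Missing-call sentinel in genotype call matrices.
MISSING = 0


@dataclass
class SnpInfo:
    """Metadata for one SNP.

    The canonical identifier is ``"<chromosome>_<position-in-bp>"``
    (e.g. ``"3_66596"``); positions are 1-based.
    """

    id: str
    chromosome: str
    position: int
    maf: float
    major_allele: Optional[str] = None
    minor_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.position}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.id}: maf must lie in [0, 0.5], got {self.maf}")

    @staticmethod
    def canonical_id(chromosome, position) -> str:
        return f"{chromosome}_{int(position)}"


class GenotypeMatrix:
    """Inbred biallelic panel: accessions x SNPs with -1/+1 calls.

    Parameters
    ----------
    accession_ids : sequence of unique labels, length n.
    snps : sequence of :class:`SnpInfo`, length m, sorted by
        (chromosome, position).
    calls : (n, m) int8 array with values in {-1, +1, MISSING}.
    """

    def __init__(self, accession_ids: Sequence[str], snps: Sequence[SnpInfo],
                 calls: np.ndarray, validate: bool = True):
        self.accession_ids = list(map(str, accession_ids))
        self.snps = list(snps)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs")
        self.calls = calls
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids are not unique")
        bad = ~np.isin(self.calls, (-1, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-homozygous call {self.calls[i, j]} at accession "
                f"{self.accession_ids[i]}, SNP {self.snps[j].id}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def m(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix(n={self.n}, m={self.m})"

    # -- frequencies ----------------------------------------------------
    def maf(self) -> np.ndarray:
        """Observed frequency of the +1 (minor) homozygote per SNP,
        over non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(n_obs > 0,
                            ((self.calls == 1).sum(axis=0)) / np.maximum(n_obs, 1),
                            np.nan)
        return freq

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    # -- selection ------------------------------------------------------
    def select_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        snps = [self.snps[int(i)] for i in index]
        return GenotypeMatrix(self.accession_ids, snps,
                              self.calls[:, index], validate=False)

    def select_accessions(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.accession_ids[int(i)] for i in index]
        return GenotypeMatrix(ids, self.snps, self.calls[index, :],
                              validate=False)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (self.accession_ids == other.accession_ids
                and self.snp_ids == other.snp_ids
                and [s.position for s in self.snps] == [s.position for s in other.snps]
                and np.array_equal(self.calls, other.calls))


@dataclass
class SeedlingRecord:
    """One seedling measurement from the plate design."""

    accession_id: str
    set_id: int
    replicate_id: int
    root_length: float
    hypocotyl_length: Optional[float] = None
    is_control: bool = False
    qc_flags: str = ""

    def __post_init__(self) -> None:
        if self.root_length < 0:
            raise ValueError("root_length must be >= 0")


#: Mandatory columns of a seedling table.
SEEDLING_COLUMNS = ("accession_id", "set_id", "replicate_id", "root_length")
SEEDLING_OPTIONAL = ("hypocotyl_length", "is_control", "qc_flags")


@dataclass
class AccessionPhenotype:
    """Per-accession summary of standardized root length (mm)."""

    accession_id: str
    mean: float
    variance: Optional[float]
    n_seedlings: int

    def __post_init__(self) -> None:
        if self.n_seedlings < 1:
            raise ValueError("n_seedlings must be >= 1")
        if self.variance is not None and self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.variance is not None and self.n_seedlings < 2:
            raise ValueError("variance requires n_seedlings >= 2")


class KinshipMatrix:
    """Labelled symmetric positive semidefinite relationship matrix."""

    SYM_TOL = 1e-10
    PSD_TOL = 1e-8

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 validate: bool = True):
        self.labels = list(map(str, labels))
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("kinship shape does not match labels")
        self.values = values
        if validate:
            self._validate()

    def _validate(self) -> None:
        v = self.values
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > self.SYM_TOL * scale:
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh((v + v.T) / 2.0)
        if w.min() < -self.PSD_TOL * max(w.max(), 1.0):
            raise ValueError(
                f"kinship matrix is not positive semidefinite "
                f"(min eigenvalue {w.min():.3e})")

    @property
    def n(self) -> int:
        return len(self.labels)

    def hadamard_square(self) -> "KinshipMatrix":
        """Entrywise square G∘G (PSD by the Schur product theorem)."""
        return KinshipMatrix(self.labels, self.values * self.values,
                             validate=False)


@dataclass
class ScanConfig:
    """Tuning knobs of the scan pipeline with the study's defaults."""

    maf_min: float = 0.25            # strict > filter for the pair scan
    min_class_count: int = 4         # minimum two-locus genotype class size
    prefilter_p: float = 1e-8        # OLS interaction p retained if <= this
    genome_length_bp: float = 125e6  # A. thaliana genome size
    ld_block_bp: float = 1e4         # average LD-block extent
    alpha: float = 0.05
    link_r2: float = 0.8             # r2 at/above which SNPs count as linked
    ld_window_bp: float = 1e4        # window for local-LD candidate search
    n_perm: int = 1000               # permutations for the HEM threshold
    n_boot_r2: int = 1000            # bootstrap reps for R2 CIs
    apparent_reps: int = 50          # bootstrap reps for apparent-epistasis LD
    apparent_threshold: float = 0.8  # r2_max exceedance threshold
    n_axes: int = 3                  # kinship eigenvectors for structure adjustment
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_class_count", "n_perm", "n_boot_r2", "apparent_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
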