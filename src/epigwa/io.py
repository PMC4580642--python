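"""Readers and writers for the pipeline's standard formats.

Genotypes travel as PLINK bed/bim/fam, VCF (plain or bgzipped) or a plain
delimited accession-by-SNP matrix; seedling tables as delimited text or
XLSX; results as tab-separated files plus a JSON run manifest.

All readers deliver the inbred -1/+1 coding of :class:`~epigwa.datatypes.
GenotypeMatrix`: +1 is the panel-minor homozygote.  Heterozygous calls are
rejected by default (the panel is fully inbred) or set missing under the
``"missing"`` policy.  SNPs with more than ``max_missing`` missing calls
are dropped at load with a logged count.
"""
from __future__ import annotations

import gzip
import json
import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (MISSING, GenotypeMatrix, SeedlingRecord, SnpInfo,
                        SEEDLING_COLUMNS, SEEDLING_OPTIONAL)

logger = logging.getLogger(__name__)

_FORMATS = ("plink", "vcf", "matrix")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def _finalize(accession_ids: Sequence[str], snps: List[SnpInfo],
              calls: np.ndarray, max_missing: float = 0.05) -> GenotypeMatrix:
    """Apply minor-allele coding, missingness filter and positional sort."""
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]

    # drop SNPs with too many missing calls
    miss = (calls == MISSING).mean(axis=0)
    keep = miss <= max_missing
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d SNPs with >%g%% missing calls",
                    n_drop, 100 * max_missing)
        calls = calls[:, keep]
        snps = [s for s, k in zip(snps, keep) if k]

    # re-normalize so +1 is the panel-minor homozygote
    for j, snp in enumerate(snps):
        col = calls[:, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        freq_plus = float((col == 1).sum()) / n_obs if n_obs else 0.0
        flip = freq_plus > 0.5
        if freq_plus == 0.5:
            # tie: the alphabetically earlier allele label is "minor";
            # without labels, keep the current orientation (column order).
            a_plus = snp.minor_allele
            a_minus = snp.major_allele
            if a_plus is not None and a_minus is not None:
                flip = a_minus < a_plus
        if flip:
            calls[obs, j] = -col[obs]
            snp.major_allele, snp.minor_allele = snp.minor_allele, snp.major_allele
            freq_plus = 1.0 - freq_plus
        snp.maf = freq_plus

    order = sorted(range(len(snps)),
                   key=lambda j: (_chrom_sort_key(snps[j].chromosome),
                                  snps[j].position))
    snps = [snps[j] for j in order]
    calls = calls[:, order]
    return GenotypeMatrix(accession_ids, snps, calls)


def _parse_snp_id(snp_id: str, index: int):
    """Split a canonical "chrom_pos" id; fall back to a synthetic position."""
    parts = str(snp_id).rsplit("_", 1)
    if len(parts) == 2:
        try:
            return parts[0], int(parts[1])
        except ValueError:
            pass
    return "0", index + 1


# ---------------------------------------------------------------------------
# delimited matrix dialect
# ---------------------------------------------------------------------------

def _read_matrix(path, max_missing: float) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    accession_ids = [str(i) for i in df.index]
    snps = []
    for j, snp_id in enumerate(df.columns):
        chrom, pos = _parse_snp_id(snp_id, j)
        snps.append(SnpInfo(id=str(snp_id), chromosome=chrom, position=pos,
                            maf=0.0))
    vals = df.to_numpy()
    calls = np.zeros(vals.shape, dtype=np.int8)
    numeric = pd.DataFrame(vals).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~(np.isin(numeric, (-1.0, 1.0)) | np.isnan(numeric))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-homozygous call {vals[i, j]!r} at accession "
            f"{accession_ids[i]}, SNP {df.columns[j]}: matrix dialect "
            f"accepts only -1, +1 and missing")
    calls[numeric == 1.0] = 1
    calls[numeric == -1.0] = -1
    return _finalize(accession_ids, snps, calls, max_missing)


def _write_matrix(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.calls.astype(float), index=gm.accession_ids,
                      columns=gm.snp_ids)
    df[gm.calls == MISSING] = np.nan
    df.index.name = "accession_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

def _read_vcf(path, het_policy: str, max_missing: float) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    n = len(accession_ids)
    snps: List[SnpInfo] = []
    columns: List[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic site {var.CHROM}:{var.POS} is not supported")
        gt = var.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        col = np.zeros(n, dtype=np.int8)
        het = gt == 1
        if het.any():
            if het_policy == "reject":
                i = int(np.flatnonzero(het)[0])
                raise ValueError(
                    f"heterozygous call at {var.CHROM}:{var.POS} "
                    f"(accession {accession_ids[i]}); the panel must be "
                    f"inbred (use het_policy='missing' to mask)")
            col[het] = MISSING
        col[gt == 0] = -1   # provisional: REF = major
        col[gt == 3] = 1
        snps.append(SnpInfo(
            id=SnpInfo.canonical_id(var.CHROM, var.POS),
            chromosome=str(var.CHROM), position=int(var.POS), maf=0.0,
            major_allele=var.REF, minor_allele=var.ALT[0]))
        columns.append(col)
    vcf.close()
    if not snps:
        raise ValueError(f"no variants found in {path}")
    calls = np.stack(columns, axis=1)
    return _finalize(accession_ids, snps, calls, max_missing)


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chromosome for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        code = {-1: "0/0", 1: "1/1", MISSING: "./."}
        # placeholder labels obey the tie rule (minor sorts first), so a
        # MAF = 0.5 SNP keeps its orientation across a write/read cycle
        for j, snp in enumerate(gm.snps):
            ref = snp.major_allele or "T"
            alt = snp.minor_allele or "A"
            gts = "\t".join(code[int(c)] for c in gm.calls[:, j])
            fh.write(f"{snp.chromosome}\t{snp.position}\t{snp.id}\t{ref}\t"
                     f"{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam dialect (2-bit packed, SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit codes, pairs packed LSB-first: 00 hom A1 (minor), 01 missing,
# 10 het, 11 hom A2 (major)
_BED_CODE = {1: 0b00, MISSING: 0b01, -1: 0b11}
_BED_DECODE = {0b00: 1, 0b01: MISSING, 0b10: 2, 0b11: -1}  # 2 marks a het


def _plink_paths(prefix):
    prefix = str(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if prefix.endswith(ext):
            prefix = prefix[: -len(ext)]
            break
    return prefix + ".bed", prefix + ".bim", prefix + ".fam"


def _read_plink(prefix, het_policy: str, max_missing: float) -> GenotypeMatrix:
    bed_path, bim_path, fam_path = _plink_paths(prefix)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    accession_ids = fam["iid"].tolist()
    n, m = len(accession_ids), len(bim)
    bytes_per_snp = (n + 3) // 4
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{bed_path}: not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * bytes_per_snp:
        raise ValueError(f"{bed_path}: size does not match {n} samples x {m} SNPs")
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit pairs, LSB first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]  # (m, n)
    decode = np.array([1, MISSING, 2, -1], dtype=np.int8)
    calls = decode[codes].T.copy()  # (n, m)
    het = calls == 2
    if het.any():
        if het_policy == "reject":
            i, j = np.argwhere(het)[0]
            raise ValueError(
                f"heterozygous call at SNP {bim['id'].iloc[j]} "
                f"(accession {accession_ids[i]}); the panel must be inbred")
        calls[het] = MISSING
    snps = []
    for j, row in bim.iterrows():
        snps.append(SnpInfo(id=str(row["id"]), chromosome=str(row["chrom"]),
                            position=int(row["pos"]), maf=0.0,
                            minor_allele=str(row["a1"]),
                            major_allele=str(row["a2"])))
    return _finalize(accession_ids, snps, calls, max_missing)


def _write_plink(gm: GenotypeMatrix, prefix) -> None:
    bed_path, bim_path, fam_path = _plink_paths(prefix)
    n, m = gm.n, gm.m
    code = np.empty(gm.calls.shape, dtype=np.uint8)
    for val, c in _BED_CODE.items():
        code[gm.calls == val] = c
    code = code.T  # (m, n)
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), _BED_CODE[MISSING], dtype=np.uint8)
    padded[:, :n] = code
    packed = (padded[:, 0::4]
              | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4)
              | (padded[:, 3::4] << 6)).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(bim_path, "w") as fh:
        for s in gm.snps:
            a1 = s.minor_allele or "A"
            a2 = s.major_allele or "T"
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\t{a1}\t{a2}\n")
    with open(fam_path, "w") as fh:
        for acc in gm.accession_ids:
            fh.write(f"{acc}\t{acc}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# public genotype API
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "matrix", het_policy: str = "reject",
                   max_missing: float = 0.05) -> GenotypeMatrix:
    """Load a genotype panel from any supported dialect.

    Parameters
    ----------
    format : one of ``"plink"``, ``"vcf"``, ``"matrix"``.
    het_policy : ``"reject"`` (default — the panel is inbred) or
        ``"missing"`` to mask heterozygous calls.
    max_missing : SNPs with a larger missing fraction are dropped.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown genotype format {format!r}; "
                         f"expected one of {_FORMATS}")
    if het_policy not in ("reject", "missing"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if format == "matrix":
        return _read_matrix(path, max_missing)
    if format == "vcf":
        return _read_vcf(path, het_policy, max_missing)
    return _read_plink(path, het_policy, max_missing)


def write_genotypes(gm: GenotypeMatrix, path, format: str = "matrix") -> None:
    """Write a panel in the named dialect (``path`` is a prefix for plink)."""
    if format == "matrix":
        _write_matrix(gm, path)
    elif format == "vcf":
        _write_vcf(gm, path)
    elif format == "plink":
        _write_plink(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}; "
                         f"expected one of {_FORMATS}")


# ---------------------------------------------------------------------------
# seedling tables
# ---------------------------------------------------------------------------

_SEEDLING_ALIASES = {
    "accession": "accession_id", "set": "set_id", "replicate": "replicate_id",
    "root_length_mm": "root_length", "hypocotyl_mm": "hypocotyl_length",
    "hypocotyl": "hypocotyl_length",
}


def read_seedlings(path) -> pd.DataFrame:
    """Read a seedling measurement table (delimited text or XLSX).

    Returns a DataFrame with the canonical seedling columns; one row per
    seedling.  Missing hypocotyl measurements are permitted.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    df = df.rename(columns=lambda c: _SEEDLING_ALIASES.get(str(c).strip().lower(),
                                                           str(c).strip().lower()))
    missing = [c for c in SEEDLING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"seedling table lacks mandatory column(s) {missing}; "
            f"columns found: {list(df.columns)}")
    for c in SEEDLING_OPTIONAL:
        if c not in df.columns:
            df[c] = np.nan if c == "hypocotyl_length" else (
                False if c == "is_control" else "")
    df["accession_id"] = df["accession_id"].astype(str)
    df["set_id"] = df["set_id"].astype(int)
    df["replicate_id"] = df["replicate_id"].astype(int)
    df["root_length"] = df["root_length"].astype(float)
    df["is_control"] = df["is_control"].astype(bool)
    if (df["root_length"] < 0).any():
        raise ValueError("negative root_length in seedling table")
    return df[list(SEEDLING_COLUMNS) + list(SEEDLING_OPTIONAL)]


def seedlings_to_records(df: pd.DataFrame) -> List[SeedlingRecord]:
    """Typed view of a seedling table."""
    out = []
    for row in df.itertuples(index=False):
        hyp = row.hypocotyl_length
        out.append(SeedlingRecord(
            accession_id=str(row.accession_id), set_id=int(row.set_id),
            replicate_id=int(row.replicate_id),
            root_length=float(row.root_length),
            hypocotyl_length=None if pd.isna(hyp) else float(hyp),
            is_control=bool(row.is_control), qc_flags=str(row.qc_flags or "")))
    return out


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------

def write_results(tables: Dict[str, pd.DataFrame], out_dir,
                  config: Optional[dict] = None,
                  seed: Optional[int] = None) -> Dict[str, str]:
    """Write result tables as TSV plus a JSON run manifest.

    Column order is the DataFrame's own (deterministic for all pipeline
    results); the manifest records the configuration and seed so a rerun
    is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    paths: Dict[str, str] = {}
    for name, table in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p
    manifest = {"tables": sorted(tables), "config": config or {}, "seed": seed}
    mp = os.path.join(out_dir, "manifest.json")
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = mp
    return paths


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
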