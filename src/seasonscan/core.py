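"""Core data containers for pooled allele-frequency time series.

The central object is :class:`AlleleFrequencyMatrix`: a SNP x sample matrix of
alt-allele frequencies estimated from pooled sequencing, together with the
per-cell read depths and the per-sample number of pooled chromosomes. Pool-seq
estimates carry two layers of sampling noise (pooling of individuals, then
sequencing of reads); the effective number of independently observed
chromosomes at a site is

    N_eff = (n_reads * n_chrs - 1) / (n_reads + n_chrs)

which is used throughout as the binomial sample size for that frequency
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlleleFrequencyMatrix",
    "effective_coverage",
    "read_af_table",
    "read_metadata",
    "read_vcf_af",
]


def effective_coverage(n_reads, n_chrs):
    """Effective number of chromosomes observed given read depth and pool size.

    ``(n_reads * n_chrs - 1) / (n_reads + n_chrs)`` — symmetric in its two
    arguments, and strictly below ``min(n_reads, n_chrs)`` whenever both
    exceed 1. Accepts scalars or arrays (broadcast).

    Raises
    ------
    ValueError
        If any input is negative.
    """
    n_reads = np.asarray(n_reads, dtype=float)
    n_chrs = np.asarray(n_chrs, dtype=float)
    if np.any(n_reads < 0) or np.any(n_chrs < 0):
        raise ValueError("read depth and chromosome counts must be non-negative")
    denom = n_reads + n_chrs
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (n_reads * n_chrs - 1.0) / denom, 0.0)
    out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AlleleFrequencyMatrix:
    """SNP x sample alt-allele frequencies with depths and pool sizes.

    Attributes
    ----------
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, ref, alt``; positions are
        1-based and strictly increasing within a chromosome.
    samples : list of str
        Sample identifiers (column order of ``af``/``depth``).
    af : ndarray, shape (n_snps, n_samples)
        Alt-allele frequency in [0, 1]; NaN marks missing cells.
    depth : ndarray, shape (n_snps, n_samples)
        Read depth per cell (>= 0).
    n_chrs : ndarray, shape (n_samples,)
        Number of pooled chromosomes per sample.
    """

    snps: pd.DataFrame
    samples: list
    af: np.ndarray
    depth: np.ndarray
    n_chrs: np.ndarray

    def __post_init__(self):
        self.af = np.asarray(self.af, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.n_chrs = np.asarray(self.n_chrs, dtype=float)
        self.samples = list(self.samples)
        n_snps, n_samples = self.af.shape
        if len(self.snps) != n_snps:
            raise ValueError("snps table and af matrix disagree on SNP count")
        if self.depth.shape != self.af.shape:
            raise ValueError("af and depth shapes differ")
        if len(self.samples) != n_samples or len(self.n_chrs) != n_samples:
            raise ValueError("sample dimension mismatch")
        valid = self.af[~np.isnan(self.af)]
        if valid.size and (valid.min() < -1e-12 or valid.max() > 1 + 1e-12):
            raise ValueError("allele frequencies outside [0, 1]")
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_snps(self):
        return self.af.shape[0]

    @property
    def n_samples(self):
        return self.af.shape[1]

    def neff(self):
        """Per-cell effective coverage N_eff (SNP x sample)."""
        return effective_coverage(self.depth, self.n_chrs[None, :])

    def mean_neff(self):
        """Per-sample mean N_eff across SNPs (ignoring missing cells)."""
        ne = self.neff()
        ne = np.where(np.isnan(self.af), np.nan, ne)
        with np.errstate(invalid="ignore"):
            return np.nanmean(ne, axis=0)

    def take_snps(self, index):
        """Subset SNPs (positional boolean mask or integer indices)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AlleleFrequencyMatrix(
            snps=self.snps.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            af=self.af[idx],
            depth=self.depth[idx],
            n_chrs=self.n_chrs,
        )

    def take_samples(self, index):
        """Subset samples by positional indices, boolean mask, or names."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        elif idx.dtype.kind in "UO":
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in idx])
        return AlleleFrequencyMatrix(
            snps=self.snps.copy(),
            samples=[self.samples[i] for i in idx],
            af=self.af[:, idx],
            depth=self.depth[:, idx],
            n_chrs=self.n_chrs[idx],
        )

    def folded_maf(self):
        """Across-sample mean of the folded (minor-allele) frequency per SNP."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.af, axis=1)
        return np.minimum(p, 1.0 - p)

    # ---------------------------------------------------------- persistence
    def to_tsv(self, path):
        """Write the wide TSV layout: chrom pos ref alt, AF_<s>, DP_<s> columns.

        Pool sizes travel in a ``#n_chrs`` header comment line.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("#n_chrs\t" + "\t".join(f"{s}={int(c)}" for s, c in zip(self.samples, self.n_chrs)) + "\n")
            cols = ["chrom", "pos", "ref", "alt"]
            header = cols + [f"AF_{s}" for s in self.samples] + [f"DP_{s}" for s in self.samples]
            fh.write("\t".join(header) + "\n")
            df = self.snps[cols].copy()
            for j, s in enumerate(self.samples):
                df[f"AF_{s}"] = self.af[:, j]
            for j, s in enumerate(self.samples):
                df[f"DP_{s}"] = self.depth[:, j].astype(int)
            df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
        return path


def read_af_table(path):
    """Read the wide AF/DP TSV written by :meth:`AlleleFrequencyMatrix.to_tsv`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#n_chrs"):
        raise ValueError(f"{path}: missing #n_chrs header line")
    pairs = [tok.split("=") for tok in first.split("\t")[1:]]
    n_chrs_map = {name: float(val) for name, val in pairs}
    df = pd.read_csv(path, sep="\t", skiprows=1)
    samples = [c[3:] for c in df.columns if c.startswith("AF_")]
    af = df[[f"AF_{s}" for s in samples]].to_numpy(float)
    depth = df[[f"DP_{s}" for s in samples]].to_numpy(float)
    snps = df[["chrom", "pos", "ref", "alt"]].copy()
    n_chrs = np.array([n_chrs_map[s] for s in samples])
    return AlleleFrequencyMatrix(snps=snps, samples=samples, af=af, depth=depth, n_chrs=n_chrs)


def read_metadata(path):
    """Read sample metadata TSV (sample, locality, date, year[, cluster, n_chrs])."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "locality", "date", "year"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta["date"] = pd.to_datetime(meta["date"])
    return meta


def read_vcf_af(path, n_chrs):
    """Build an AF matrix from a VCF with AD (or AD-free GT) FORMAT fields.

    Alt AF is AD_alt / (AD_ref + AD_alt) where AD is available; depth is DP or
    the AD sum. ``n_chrs`` maps sample name -> pooled chromosome count (or a
    scalar applied to all samples).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env provides cyvcf2
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if np.isscalar(n_chrs):
        nch = np.full(len(samples), float(n_chrs))
    else:
        nch = np.array([float(n_chrs[s]) for s in samples])
    rows, afs, dps = [], [], []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            continue
        ad = ad.astype(float)
        ad[ad < 0] = np.nan
        tot = ad[:, 0] + ad[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(tot > 0, ad[:, 1] / tot, np.nan)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        afs.append(af)
        dps.append(np.nan_to_num(tot))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return AlleleFrequencyMatrix(
        snps=snps, samples=samples, af=np.array(afs), depth=np.array(dps), n_chrs=nch
    )
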