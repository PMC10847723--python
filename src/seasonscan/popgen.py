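"""Individual-sequence population-genetic statistics and matched controls.

Windowed diversity statistics operate on a haplotype matrix (sequences x
sites, 0/1 alleles): pi is the per-window sum of mean pairwise differences
(the windowed-sum convention of vcftools' --window-pi; divide by accessible
sites for per-site values), Tajima's D uses the standard a1/a2/b/c/e
constants, and the haplotype count is the number of distinct allele strings.
FST between karyotype classes uses the Weir-Cockerham (1984) two-population
variance-component estimator on diploid dosages, aggregated ratio-of-sums
per window. Matched controls for candidate SNPs are drawn off-chromosome
within recombination-rate and global-frequency tolerance bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "nucleotide_diversity",
    "tajimas_d",
    "haplotype_count",
    "karyotype_fst",
    "pairwise_ld_scan",
    "matched_controls",
    "ControlSet",
]


def _window_mask(pos, window):
    start, end = window
    pos = np.asarray(pos)
    return (pos >= start) & (pos < end)


def nucleotide_diversity(haplotypes, pos=None, window=None):
    """Mean pairwise difference count summed over sites in the window.

    ``haplotypes``: (n_sequences, n_sites) 0/1 array. For each site with alt
    count c among n sequences the pairwise difference count is c(n-c); pi is
    the sum over sites divided by C(n, 2).
    """
    H = np.asarray(haplotypes)
    if H.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    if window is not None:
        H = H[:, _window_mask(pos, window)]
    n = H.shape[0]
    c = H.sum(axis=0)
    return float(np.sum(c * (n - c)) / (n * (n - 1) / 2))


def _tajima_constants(n):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(haplotypes, pos=None, window=None):
    """Tajima's D: (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Returns NaN when the window is monomorphic (S = 0); requires n >= 3
    sequences.
    """
    H = np.asarray(haplotypes)
    if window is not None:
        H = H[:, _window_mask(pos, window)]
    n = H.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sequences")
    c = H.sum(axis=0)
    S = int(np.sum((c > 0) & (c < n)))
    if S == 0:
        return np.nan
    pi = np.sum(c * (n - c)) / (n * (n - 1) / 2)
    a1, e1, e2 = _tajima_constants(n)
    return float((pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))


def haplotype_count(haplotypes, pos=None, window=None):
    """Number of distinct allele strings in the window."""
    H = np.asarray(haplotypes)
    if H.shape[0] < 1:
        raise ValueError("need at least 1 sequence")
    if window is not None:
        H = H[:, _window_mask(pos, window)]
    return int(np.unique(H, axis=0).shape[0])


def _wc_components(d1, d2):
    """Weir-Cockerham (1984) per-SNP a, b, c components for two diploid
    populations given dosage matrices (individuals x SNPs)."""
    r = 2
    n1, n2 = d1.shape[0], d2.shape[0]
    p1 = d1.mean(axis=0) / 2.0
    p2 = d2.mean(axis=0) / 2.0
    h1 = (d1 == 1).mean(axis=0)
    h2 = (d2 == 1).mean(axis=0)
    nbar = (n1 + n2) / 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def karyotype_fst(genotypes, calls, windows):
    """Weir-Cockerham FST between INV and STD karyotype classes per window.

    ``calls`` is a KaryotypeCall DataFrame (or any frame with ``call``
    aligned to ``genotypes.individuals``); HET individuals are excluded.
    ``windows`` is a DataFrame with ``chrom, start, end``. Per window the
    estimate is the ratio of summed a-components to summed (a+b+c); windows
    with a class absent get NaN throughout.
    """
    call = np.asarray(calls["call"]) if hasattr(calls, "columns") else np.asarray(calls)
    inv = np.flatnonzero(call == "INV")
    std = np.flatnonzero(call == "STD")
    out = windows.copy()
    if len(inv) < 2 or len(std) < 2:
        warnings.warn("fewer than 2 individuals in a karyotype class; FST undefined")
        out["fst"] = np.nan
        out["n_snps"] = 0
        return out
    D = genotypes.dosage.astype(float)
    a, b, c = _wc_components(D[inv], D[std])
    poly = (genotypes.dosage.max(axis=0) > 0) & (genotypes.dosage.min(axis=0) < 2)
    fst, nsnp = [], []
    for _, w in windows.iterrows():
        m = (
            (genotypes.chrom == w["chrom"])
            & (genotypes.pos >= w["start"])
            & (genotypes.pos < w["end"])
            & poly
        )
        if not m.any():
            fst.append(np.nan)
            nsnp.append(0)
            continue
        denom = np.sum((a + b + c)[m])
        fst.append(float(np.sum(a[m]) / denom) if denom != 0 else np.nan)
        nsnp.append(int(m.sum()))
    out["fst"] = fst
    out["n_snps"] = nsnp
    return out


def _mean_r2_between(H, idx1, idx2=None):
    X = H[:, idx1].astype(float)
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    if idx2 is None:
        keep = sx > 0
        Xc, sx = Xc[:, keep], sx[keep]
        if Xc.shape[1] < 2:
            return np.nan
        R = (Xc.T @ Xc) / np.outer(sx, sx)
        iu = np.triu_indices(R.shape[0], k=1)
        return float(np.mean(R[iu] ** 2))
    Y = H[:, idx2].astype(float)
    Yc = Y - Y.mean(axis=0)
    sy = np.sqrt((Yc**2).sum(axis=0))
    ok1, ok2 = sx > 0, sy > 0
    if not ok1.any() or not ok2.any():
        return np.nan
    R = (Xc[:, ok1].T @ Yc[:, ok2]) / np.outer(sx[ok1], sy[ok2])
    return float(np.mean(R**2))


def pairwise_ld_scan(
    haplotypes,
    chrom,
    pos,
    window_size=50_000,
    step=10_000,
    long_range_pairs=None,
    phased=True,
):
    """Mean pairwise r^2 within sliding windows (or between window pairs).

    ``haplotypes`` is sequences x SNPs for phased input; with
    ``phased=False`` the rows are diploid dosages and the statistic is the
    composite (dosage-correlation) LD, flagged in the output attrs. Windows
    with fewer than 2 SNPs get NaN. ``long_range_pairs`` is an optional list
    of ((chrom, start, end), (chrom, start, end)) interval pairs scored by
    the mean r^2 across the two SNP sets.
    """
    H = np.asarray(haplotypes)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    if long_range_pairs is not None:
        rows = []
        for w1, w2 in long_range_pairs:
            i1 = np.flatnonzero((chrom == w1[0]) & _window_mask(pos, w1[1:]))
            i2 = np.flatnonzero((chrom == w2[0]) & _window_mask(pos, w2[1:]))
            val = np.nan
            if len(i1) and len(i2):
                val = _mean_r2_between(H, i1, i2)
            rows.append({"window1": w1, "window2": w2, "mean_r2": val})
        out = pd.DataFrame(rows)
        out.attrs["composite_ld"] = not phased
        return out
    rows = []
    for c in pd.unique(chrom):
        on = chrom == c
        pmax = pos[on].max()
        start = 0
        while start <= pmax:
            idx = np.flatnonzero(on & (pos >= start) & (pos < start + window_size))
            val = _mean_r2_between(H, idx) if len(idx) >= 2 else np.nan
            rows.append({"chrom": c, "start": start, "end": start + window_size, "mean_r2": val})
            start += step
    out = pd.DataFrame(rows)
    out.attrs["composite_ld"] = not phased
    return out


@dataclass
class ControlSet:
    focal: int  # index of the focal SNP in the candidate annotation table
    controls: np.ndarray  # indices of matched control SNPs


def matched_controls(
    focal_snps,
    annotations,
    rec_tol=0.20,
    af_tol=0.030,
    k=100,
    seed=None,
):
    """Matched-control sampling for candidate SNPs.

    ``annotations`` is a DataFrame with columns ``chrom, rec_rate, af`` (one
    row per candidate-pool SNP; index = SNP id). For each focal SNP id a
    uniform sample (without replacement) of up to ``k`` SNPs is drawn from
    other chromosomes within +/-``rec_tol`` cM/Mb of the focal recombination
    rate and +/-``af_tol`` of its global allele frequency. Empty qualifying
    sets warn and yield an empty control list.
    """
    rng = np.random.default_rng(seed)
    chrom = annotations["chrom"].to_numpy()
    rec = annotations["rec_rate"].to_numpy(float)
    af = annotations["af"].to_numpy(float)
    ids = annotations.index.to_numpy()
    out = []
    for f in focal_snps:
        row = annotations.loc[f]
        ok = (
            (chrom != row["chrom"])
            & (np.abs(rec - row["rec_rate"]) <= rec_tol)
            & (np.abs(af - row["af"]) <= af_tol)
        )
        cand = ids[ok]
        if len(cand) == 0:
            warnings.warn(f"no qualifying matched controls for SNP {f}")
            out.append(ControlSet(f, np.array([], dtype=ids.dtype)))
            continue
        take = min(k, len(cand))
        sel = rng.choice(cand, size=take, replace=False)
        # tolerance contract re-checked on every emitted control
        assert (annotations.loc[sel, "chrom"] != row["chrom"]).all()
        assert (np.abs(annotations.loc[sel, "rec_rate"] - row["rec_rate"]) <= rec_tol).all()
        assert (np.abs(annotations.loc[sel, "af"] - row["af"]) <= af_tol).all()
        out.append(ControlSet(f, np.sort(sel)))
    return out
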