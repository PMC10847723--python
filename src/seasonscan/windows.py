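"""Genome-scan layer: rank normalization, window enrichment, WZA, thresholds.

Per-SNP association P-values are first rank-normalized onto the uniform grid
{1/L, ..., 1} so that downstream window statistics are calibration-free.
Sliding windows (0.1 Mb, 50 kb step; 0-based half-open internally, reported
1-based inclusive) are scored two ways:

* signal enrichment — an exact one-sided binomial test for an excess of SNPs
  belonging to the genome-wide most-significant 5%;
* WZA — the weighted-Z (Stouffer) aggregate Z = sum(w_i z_i)/sqrt(sum w_i^2)
  with z_i = Phi^{-1}(1 - p_i) and mean-frequency weights w_i = pbar*qbar
  (equal weights supported).

Significance of the real scan is judged against per-window empirical critical
values from the linkage-preserving GLM permutations (upper 1% by default),
and contiguous significant runs are collapsed into padded windows of
interest around each run's peak.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rank_normalize",
    "make_windows",
    "assign_windows",
    "signal_enrichment",
    "wza",
    "empirical_threshold",
    "windows_of_interest",
]

WINDOW_SIZE = 100_000
WINDOW_STEP = 50_000


def rank_normalize(p, chrom=None, pos=None):
    """Replace P-values by rank/L on the uniform grid {1/L, ..., 1}.

    Ties are broken by (chrom, pos) when given (documented deterministic
    policy), otherwise by input order. Missing P-values are excluded from L
    and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    L = int(ok.sum())
    if L == 0:
        return out
    idx = np.flatnonzero(ok)
    if chrom is not None and pos is not None:
        chrom = np.asarray(chrom)[idx]
        pos = np.asarray(pos)[idx]
        order = np.lexsort((pos, chrom, p[idx]))
    else:
        order = np.argsort(p[idx], kind="stable")
    ranks = np.empty(L)
    ranks[order] = np.arange(1, L + 1)
    out[idx] = ranks / L
    return out


def make_windows(chrom, pos, size=WINDOW_SIZE, step=WINDOW_STEP):
    """Sliding windows tiling each chromosome from coordinate 0.

    Starts at 0, step, 2*step, ...; 0-based half-open [start, end). Returns a
    DataFrame ``chrom, start, end`` covering every SNP at least once.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    rows = []
    for c in pd.unique(chrom):
        pmax = pos[chrom == c].max()
        start = 0
        while start <= pmax:
            rows.append((c, start, start + size))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_windows(windows, chrom, pos):
    """List of SNP index arrays, one per window row (0-based half-open)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = []
    for _, w in windows.iterrows():
        mask = (chrom == w["chrom"]) & (pos >= w["start"]) & (pos < w["end"])
        out.append(np.flatnonzero(mask))
    return out


def signal_enrichment(ranked_p, windows, members, top_q=0.05):
    """Per-window exact binomial test for excess top-``top_q`` SNPs.

    Top-set membership is decided once genome-wide (rank-normalized p <=
    ``top_q``), then counted per window; the one-sided (greater) binomial
    tail P(X >= n_top | n_snps, top_q) is reported. Empty windows get NaN.

    Returns ``windows`` with added columns ``n_snps, n_top, binom_p``.
    """
    ranked_p = np.asarray(ranked_p, dtype=float)
    top = ranked_p <= top_q
    n_snps = np.array([len(m) for m in members])
    n_top = np.array([int(top[m].sum()) for m in members])
    with np.errstate(invalid="ignore"):
        pvals = sps.binom.sf(n_top - 1, np.maximum(n_snps, 1), top_q)
    pvals = np.where(n_snps > 0, pvals, np.nan)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["n_top"] = n_top
    out["binom_p"] = pvals
    return out


def wza(p, windows, members, maf=None, equal_weights=False):
    """Weighted-Z aggregation of per-SNP P-values within windows.

    ``Z = sum(w_i z_i) / sqrt(sum w_i^2)`` with ``z_i = Phi^-1(1 - p_i)``.
    Default weights are ``pbar*qbar`` from the per-SNP mean allele frequency
    ``maf``; ``equal_weights=True`` uses w_i = 1. Degenerate p (0 or 1) is
    clamped to [1/(10L), 1 - 1/(10L)] and flagged in the output column
    ``n_clamped``. Under uniform p and any fixed weights, Z ~ N(0, 1).
    """
    p = np.asarray(p, dtype=float)
    L = max(int(np.isfinite(p).sum()), 1)
    lo, hi = 1.0 / (10 * L), 1.0 - 1.0 / (10 * L)
    clamped = (p <= 0) | (p >= 1)
    pc = np.where(p <= 0, lo, np.where(p >= 1, hi, p))
    z = sps.norm.isf(pc)
    if equal_weights or maf is None:
        w = np.ones_like(p)
    else:
        maf = np.asarray(maf, dtype=float)
        w = maf * (1 - maf)
    out = windows.copy()
    zs, ncl = [], []
    for m in members:
        m = m[np.isfinite(p[m])]
        if len(m) == 0 or np.sum(w[m] ** 2) == 0:
            zs.append(np.nan)
            ncl.append(0)
            continue
        if np.all(w[m] == 0):
            raise ValueError("all-zero weights in a non-empty window")
        zs.append(float(np.sum(w[m] * z[m]) / np.sqrt(np.sum(w[m] ** 2))))
        ncl.append(int(clamped[m].sum()))
    out["wza_z"] = zs
    out["n_clamped"] = ncl
    out.attrs["weights"] = "equal" if (equal_weights or maf is None) else "pbar_qbar"
    return out


def empirical_threshold(perm_scores, level=0.99):
    """Per-window upper quantile of permutation scores.

    ``perm_scores``: array (n_perm, n_windows) of scores where larger means
    more extreme (e.g. -log10 binomial p, or WZA Z). A window beats
    permutations when its real score exceeds its critical value. With fewer
    than 20 permutations the per-window maximum is used, with a warning.
    """
    perm_scores = np.asarray(perm_scores, dtype=float)
    n_perm = perm_scores.shape[0]
    if n_perm < 20:
        warnings.warn(
            f"only {n_perm} permutations for the {level:.0%} threshold; using the maximum"
        )
        return np.nanmax(perm_scores, axis=0)
    return np.nanquantile(perm_scores, level, axis=0)


def windows_of_interest(windows, scores, thresholds, pad=200_000):
    """Padded intervals around peaks of contiguous significant windows.

    Finds runs of consecutive windows (per chromosome, in genomic order)
    whose score exceeds the threshold, takes the maximum-score window's
    center per run, and emits [center - pad, center + pad]; overlapping
    intervals on one chromosome are merged. Returns a DataFrame
    ``chrom, start, end, peak_center, peak_score`` (possibly empty).
    """
    scores = np.asarray(scores, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(scores) != len(windows) or len(thresholds) != len(windows):
        raise ValueError("scores/thresholds must align with windows")
    sig = scores > thresholds
    rows = []
    for c in pd.unique(windows["chrom"]):
        widx = np.flatnonzero((windows["chrom"] == c).to_numpy())
        widx = widx[np.argsort(windows["start"].to_numpy()[widx])]
        run = []
        for i, wi in enumerate(widx):
            if sig[wi]:
                run.append(wi)
            if run and (not sig[wi] or i == len(widx) - 1):
                peak = run[int(np.argmax(scores[run]))]
                center = (windows["start"].iloc[peak] + windows["end"].iloc[peak]) / 2.0
                rows.append(
                    {
                        "chrom": c,
                        "start": max(0, center - pad),
                        "end": center + pad,
                        "peak_center": center,
                        "peak_score": scores[peak],
                    }
                )
                run = []
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_center", "peak_score"])
    if out.empty:
        return out
    merged = []
    for c, grp in out.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is None or r["start"] > cur["end"]:
                if cur is not None:
                    merged.append(cur)
                cur = r.to_dict()
            else:
                if r["peak_score"] > cur["peak_score"]:
                    cur["peak_center"], cur["peak_score"] = r["peak_center"], r["peak_score"]
                cur["end"] = max(cur["end"], r["end"])
        merged.append(cur)
    return pd.DataFrame(merged)
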