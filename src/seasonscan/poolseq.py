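"""Pool-seq analyses: filtering, pool FST, PCA ordination, and DAPC.

Pool FST uses the two-level analysis-of-variance (method-of-moments)
estimator with the per-sample effective coverage N_eff standing in for the
number of sampled chromosomes. For two pools with effective sizes n1, n2 and
allele frequencies p1, p2 the per-SNP components are

    MSP = n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2          (between pools)
    MSG = [n1 p1 q1 + n2 p2 q2] / (n1 + n2 - 2)        (within pools)
    n_c = n1 + n2 - (n1^2 + n2^2) / (n1 + n2)

    FST = (MSP - MSG) / (MSP + (n_c - 1) MSG)

and the genome-wide value is the ratio of summed numerators to summed
denominators (not the mean of per-SNP ratios), which keeps the aggregate
unbiased even though individual per-SNP estimates can be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlleleFrequencyMatrix

__all__ = [
    "FilterReport",
    "filter_snps",
    "pool_fst",
    "pca_ordinate",
    "pc_correlation_profile",
    "dapc",
]


@dataclass
class FilterReport:
    n_samples_in: int
    n_samples_dropped: int
    n_snps_in: int
    n_snps_dropped: int
    dropped_samples: list


def filter_snps(afm: AlleleFrequencyMatrix, maf_min=0.01, mean_neff_min=28.0):
    """Drop low-coverage samples, then low-frequency SNPs.

    Samples whose mean N_eff is strictly below ``mean_neff_min`` are removed
    first; then SNPs whose across-sample mean folded minor-allele frequency is
    strictly below ``maf_min`` are removed.

    Returns ``(filtered_afm, FilterReport)``. An empty result warns rather
    than raising.
    """
    if maf_min < 0 or mean_neff_min < 0:
        raise ValueError("thresholds must be non-negative")
    mean_ne = afm.mean_neff()
    keep_samples = mean_ne >= mean_neff_min
    dropped = [s for s, k in zip(afm.samples, keep_samples) if not k]
    out = afm.take_samples(keep_samples) if not keep_samples.all() else afm
    if out.n_samples == 0:
        warnings.warn("all samples removed by mean-Neff filter")
        report = FilterReport(afm.n_samples, len(dropped), afm.n_snps, afm.n_snps, dropped)
        return out.take_snps(np.zeros(out.n_snps, dtype=bool)), report
    maf = out.folded_maf()
    keep_snps = maf >= maf_min
    out2 = out.take_snps(keep_snps)
    if out2.n_snps == 0:
        warnings.warn("all SNPs removed by MAF filter")
    report = FilterReport(
        n_samples_in=afm.n_samples,
        n_samples_dropped=len(dropped),
        n_snps_in=afm.n_snps,
        n_snps_dropped=int((~keep_snps).sum()),
        dropped_samples=dropped,
    )
    return out2, report


def _fst_components(p1, p2, n1, n2):
    """Per-SNP ANOVA numerator/denominator for a pair of pools."""
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
    num = msp - msg
    den = msp + (nc - 1) * msg
    return num, den


def pool_fst(afm: AlleleFrequencyMatrix, sample_pair, min_depth=1.0):
    """Pool-seq FST between two samples.

    Parameters
    ----------
    sample_pair : tuple
        Two sample names (or integer column indices).
    min_depth : float
        SNPs with depth below this in either sample are excluded.

    Returns
    -------
    (per_snp, genome_wide) : (ndarray, float)
        Per-SNP estimates (NaN where undefined; negative values retained) and
        the ratio-of-sums genome-wide estimate.
    """
    idx = []
    for s in sample_pair:
        if isinstance(s, (int, np.integer)):
            idx.append(int(s))
        else:
            idx.append(afm.samples.index(s))
    i, j = idx
    p1, p2 = afm.af[:, i], afm.af[:, j]
    ne = afm.neff()
    n1, n2 = ne[:, i], ne[:, j]
    ok = (
        ~np.isnan(p1)
        & ~np.isnan(p2)
        & (afm.depth[:, i] >= min_depth)
        & (afm.depth[:, j] >= min_depth)
        & (n1 + n2 > 2)
    )
    if not ok.any():
        raise ValueError("no overlapping covered SNPs between the two samples")
    num = np.full(afm.n_snps, np.nan)
    den = np.full(afm.n_snps, np.nan)
    num[ok], den[ok] = _fst_components(p1[ok], p2[ok], n1[ok], n2[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(den != 0, num / den, np.nan)
    gw = float(np.nansum(num) / np.nansum(den))
    return per_snp, gw


def _prep_matrix(afm, snp_subset=None, rng=None):
    """Sample x SNP matrix, mean-imputed per SNP, optionally SNP-subsampled."""
    af = afm.af
    if snp_subset is not None:
        if np.isscalar(snp_subset):
            k = int(snp_subset)
            if k > afm.n_snps:
                raise ValueError(f"requested {k} SNPs but matrix has {afm.n_snps}")
            rng = np.random.default_rng() if rng is None else rng
            snp_subset = rng.choice(afm.n_snps, size=k, replace=False)
        af = af[np.asarray(snp_subset)]
    X = af.T.copy()  # samples x snps
    col_mean = np.nanmean(X, axis=0)
    nanmask = np.isnan(X)
    if nanmask.any():
        X[nanmask] = np.take(col_mean, np.where(nanmask)[1])
    return X


def pca_ordinate(afm: AlleleFrequencyMatrix, snp_subset=None, seed=None, n_pcs=3):
    """PCA of samples on (column-centered, unscaled) allele frequencies.

    Returns a DataFrame with one row per sample: columns ``PC1..PCk`` and the
    attribute-stored percent variance explained ``.attrs['pve']``. Scores are
    sign-fixed so that each PC's largest-magnitude SNP loading is positive;
    missing frequencies are mean-imputed per SNP.
    """
    if afm.n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    rng = np.random.default_rng(seed)
    X = _prep_matrix(afm, snp_subset, rng)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, len(s))
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|loading| SNP positive on each axis
    for a in range(k):
        jmax = np.argmax(np.abs(Vt[a]))
        if Vt[a, jmax] < 0:
            scores[:, a] *= -1
            Vt[a] *= -1
    var = s**2
    pve = 100.0 * var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    out = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)], index=afm.samples)
    out.attrs["pve"] = pve
    out.attrs["loadings"] = Vt[:k]
    return out


def pc_correlation_profile(
    afm, label, subset_sizes, n_reps=20, n_perm=20, seed=None, n_pcs=3
):
    """Correlation of PCs 1-3 with a per-sample label across SNP subset sizes.

    For each subset size and replicate, draws that many SNPs at random, runs
    PCA, and records the Pearson correlation of each retained PC with
    ``label``; the same is repeated with the label permuted across samples to
    build the null. Returns a long DataFrame with columns
    ``size, rep, kind ('real'|'perm'), pc, corr``.
    """
    label = np.asarray(label, dtype=float)
    if np.nanstd(label) == 0:
        raise ValueError("label is constant across samples")
    rng = np.random.default_rng(seed)
    rows = []
    for size in subset_sizes:
        if size > afm.n_snps:
            raise ValueError(f"subset size {size} exceeds SNP count {afm.n_snps}")
        for rep in range(n_reps):
            idx = rng.choice(afm.n_snps, size=int(size), replace=False)
            scores = pca_ordinate(afm, snp_subset=idx, n_pcs=n_pcs)
            for a in range(scores.shape[1]):
                pc = scores.iloc[:, a].to_numpy()
                c = _safe_corr(pc, label)
                rows.append((size, rep, "real", a + 1, c))
        for rep in range(n_perm):
            idx = rng.choice(afm.n_snps, size=int(size), replace=False)
            perm = rng.permutation(label)
            scores = pca_ordinate(afm, snp_subset=idx, n_pcs=n_pcs)
            for a in range(scores.shape[1]):
                pc = scores.iloc[:, a].to_numpy()
                rows.append((size, rep, "perm", a + 1, _safe_corr(pc, perm)))
    return pd.DataFrame(rows, columns=["size", "rep", "kind", "pc", "corr"])


def _safe_corr(x, y):
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def dapc(afm: AlleleFrequencyMatrix, groups, n_pc_retained=None, var_target=0.80):
    """Discriminant analysis of principal components.

    PCA on the (centered) AF matrix down to ``n_pc_retained`` axes (default:
    enough axes to reach ``var_target`` of the variance), then linear
    discriminant analysis of the PC scores with ``groups`` as the prior.
    Returns a DataFrame of per-sample discriminant scores ``LD1, LD2, ...``.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    X = _prep_matrix(afm)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    if n_pc_retained is None:
        cum = np.cumsum(var) / var.sum()
        n_pc_retained = int(np.searchsorted(cum, var_target) + 1)
    if n_pc_retained >= afm.n_samples:
        raise ValueError("n_pc_retained must be below the sample count")
    scores = U[:, :n_pc_retained] * s[:n_pc_retained]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    lda.fit(scores, groups)
    ld = lda.transform(scores)
    n_ld = min(ld.shape[1], len(uniq) - 1)
    out = pd.DataFrame(
        ld[:, :n_ld], columns=[f"LD{i+1}" for i in range(n_ld)], index=afm.samples
    )
    out.attrs["n_pc_retained"] = n_pc_retained
    return out
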