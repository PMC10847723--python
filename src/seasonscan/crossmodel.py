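"""Cross-analysis enrichment and directionality statistics.

Compares top-SNP sets between analyses (an environment-association GLM scan
versus either another region's scan or GWAS summary statistics) with
Fisher's exact test, and measures the consistency of effect directions with
the "directionality" statistic: the percentage of jointly significant SNPs
whose regression-coefficient signs agree between the two analyses (null
expectation 50%; 100% and 0% both indicate block-like, coordinated
frequency change). Window-level GWAS x GLM scans use per-window Fisher tests
across phenotypes with Bonferroni correction and permutation-derived
critical counts. Inversion-phenotype association counts significant trait
models and compares the count against label-shuffling permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .windows import rank_normalize

__all__ = [
    "top_set",
    "OverlapResult",
    "fet_enrichment",
    "directionality",
    "gwas_glm_window_scan",
    "inversion_phenotype_assoc",
]


def top_set(p, q=0.05, chrom=None, pos=None):
    """Membership flags for the top-``q`` fraction of an analysis' P-values.

    Rank-normalizes within the analysis' own tested SNP set and flags
    rank/L <= q; boundary ties are resolved by (chrom, pos) when provided
    (the rank-normalization tie policy). NaN p-values are never members.
    """
    ranked = rank_normalize(p, chrom=chrom, pos=pos)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(ranked, nan=np.inf) <= q


@dataclass
class OverlapResult:
    table: np.ndarray  # [[a, b], [c, d]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    alternative: str


def fet_enrichment(set_a, set_b, universe=None, alternative="greater"):
    """Fisher's exact test for overlap of two SNP sets within a universe.

    ``set_a``/``set_b`` are boolean membership arrays over the universe
    (``universe`` optionally restricts to a boolean mask). The 2x2 table is
    [[both, A only], [B only, neither]]. The sample odds ratio uses a
    Haldane 0.5 correction when any cell is zero; the 95% CI is the Woolf
    log-OR approximation.
    """
    a = np.asarray(set_a, bool)
    b = np.asarray(set_b, bool)
    if universe is not None:
        u = np.asarray(universe, bool)
        if u.sum() == 0:
            raise ValueError("empty universe")
        a, b = a[u], b[u]
    if a.size == 0:
        raise ValueError("empty universe")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    table = np.array([[n11, n10], [n01, n00]])
    _, p = sps.fisher_exact(table, alternative=alternative)
    cells = table.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5
    orr = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    se = np.sqrt(np.sum(1.0 / cells))
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return OverlapResult(table, float(orr), float(lo), float(hi), float(p), alternative)


def directionality(betas_a, betas_b, mask_a=None, mask_b=None):
    """Percent of jointly significant SNPs with matching coefficient signs.

    Conditions on both significance masks (default: all) and excludes SNPs
    with a zero coefficient in either analysis from the denominator. Returns
    ``(percent, n)``; percent is NaN with n = 0 for an empty denominator.
    """
    ba = np.asarray(betas_a, float)
    bb = np.asarray(betas_b, float)
    m = np.ones(ba.shape, bool)
    if mask_a is not None:
        m &= np.asarray(mask_a, bool)
    if mask_b is not None:
        m &= np.asarray(mask_b, bool)
    m &= (ba != 0) & (bb != 0) & np.isfinite(ba) & np.isfinite(bb)
    n = int(m.sum())
    if n == 0:
        return np.nan, 0
    same = np.sign(ba[m]) == np.sign(bb[m])
    return float(100.0 * same.mean()), n


def gwas_glm_window_scan(
    gwas,
    glm_p,
    glm_beta,
    snps,
    windows,
    members,
    perm_glm_p=None,
    alpha=0.05,
    top_q=0.05,
):
    """Window-level enrichment of joint GWAS x GLM top hits, per phenotype.

    Parameters
    ----------
    gwas : DataFrame
        Summary table with columns ``snp, phenotype, beta, p`` (one row per
        SNP x phenotype); SNP ids index into ``snps``.
    glm_p, glm_beta : arrays over the SNP universe
        Environment-GLM P-values and covariate-slope signs.
    snps : DataFrame with ``chrom, pos`` per universe SNP.
    windows, members : sliding windows and their SNP-index lists.
    perm_glm_p : optional (n_perm, n_snps) array
        Permuted GLM P-values; enables the per-window permutation critical
        count (real count must exceed the 95th-largest permuted count).
    alpha : float
        Family-wise level for the Bonferroni correction across the whole
        window x phenotype scan.

    Returns
    -------
    (per_pheno, per_window) DataFrames: per window x phenotype Fisher
    results with Bonferroni flags, and per-window significant-phenotype
    counts (plus permutation critical values and flags when permutations are
    supplied).
    """
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    glm_top = top_set(glm_p, q=top_q, chrom=chrom, pos=pos)
    phenos = list(pd.unique(gwas["phenotype"]))
    n_univ = len(snps)
    gwas_top = {}
    for ph in phenos:
        sub = gwas[gwas["phenotype"] == ph]
        pvec = np.full(n_univ, np.nan)
        pvec[sub["snp"].to_numpy()] = sub["p"].to_numpy()
        if not np.isfinite(pvec).any():
            warnings.warn(f"phenotype {ph!r} has no SNPs in the universe; skipped")
            continue
        gwas_top[ph] = top_set(pvec, q=top_q, chrom=chrom, pos=pos)
    m_tests = len(windows) * len(gwas_top)
    bonf = alpha / m_tests if m_tests else alpha
    rows = []
    counts = np.zeros(len(windows), dtype=int)
    for wi, mem in enumerate(members):
        if len(mem) == 0:
            continue
        for ph, gt in gwas_top.items():
            res = fet_enrichment(gt[mem], glm_top[mem])
            sig = res.p_value < bonf
            counts[wi] += int(sig)
            rows.append(
                {
                    "window": wi,
                    "phenotype": ph,
                    "n_joint": int(res.table[0, 0]),
                    "odds_ratio": res.odds_ratio,
                    "fet_p": res.p_value,
                    "significant": sig,
                }
            )
    per_pheno = pd.DataFrame(rows)
    per_window = windows.copy()
    per_window["n_sig_phenotypes"] = counts
    if perm_glm_p is not None:
        n_perm = perm_glm_p.shape[0]
        perm_counts = np.zeros((n_perm, len(windows)), dtype=int)
        for k in range(n_perm):
            ptop = top_set(perm_glm_p[k], q=top_q, chrom=chrom, pos=pos)
            for wi, mem in enumerate(members):
                if len(mem) == 0:
                    continue
                for ph, gt in gwas_top.items():
                    res = fet_enrichment(gt[mem], ptop[mem])
                    perm_counts[k, wi] += int(res.p_value < bonf)
        crit = np.quantile(perm_counts, 0.95, axis=0, method="higher")
        per_window["perm_crit_count"] = crit
        per_window["beats_permutations"] = counts > crit
    return per_pheno, per_window


def inversion_phenotype_assoc(phenotypes, karyotype, n_perm=1000, seed=None, alpha=0.05):
    """Association of line-mean phenotypes with inversion status.

    ``phenotypes``: DataFrame (lines x traits); ``karyotype``: per-line
    labels, INV/STD homozygotes only are used. Each trait is fit with the
    linear model trait ~ karyotype (equivalent to a two-sample t-test); the
    count of traits with nominal p < ``alpha`` is compared to the identical
    counting under ``n_perm`` label shuffles.

    Returns a dict with ``per_trait`` (DataFrame trait, p), ``n_significant``,
    ``perm_counts`` (ndarray), and ``exceeds_permutations`` (real count >
    95th percentile of the permutation counts).
    """
    karyo = np.asarray(karyotype)
    keep = np.isin(karyo, ["INV", "STD"])
    X = phenotypes.loc[keep]
    g = (karyo[keep] == "INV").astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need >= 2 lines per homozygous karyotype class")
    rng = np.random.default_rng(seed)
    Y = X.to_numpy(float)

    def trait_pvalues(gvec):
        # vectorized equal-variance two-sample t-test (== the linear model
        # trait ~ karyotype) across all traits at once; NaN-aware per trait
        m = np.isfinite(Y)
        n1 = (m & (gvec[:, None] == 1)).sum(axis=0)
        n0 = (m & (gvec[:, None] == 0)).sum(axis=0)
        Y0 = np.where(m, Y, 0.0)
        s1 = (Y0 * (gvec[:, None] == 1)).sum(axis=0)
        s0 = (Y0 * (gvec[:, None] == 0)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m1, m0 = s1 / n1, s0 / n0
            ss1 = (Y0**2 * (gvec[:, None] == 1)).sum(axis=0) - n1 * m1**2
            ss0 = (Y0**2 * (gvec[:, None] == 0)).sum(axis=0) - n0 * m0**2
            df = n1 + n0 - 2
            sp2 = (ss1 + ss0) / df
            t = (m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
            p = 2 * sps.t.sf(np.abs(t), df)
        bad = (n1 < 2) | (n0 < 2) | (sp2 <= 0) | ~np.isfinite(p)
        p[bad] = np.nan
        return p

    real = trait_pvalues(g)
    ok = np.isfinite(real)
    per_trait = pd.DataFrame({"trait": X.columns[ok], "p": real[ok]})
    n_sig = int((per_trait["p"] < alpha).sum())
    perm_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        p = trait_pvalues(rng.permutation(g))
        perm_counts[i] = int(np.nansum(p < alpha))
    crit = np.quantile(perm_counts, 0.95, method="higher")
    return {
        "per_trait": per_trait,
        "n_significant": n_sig,
        "perm_counts": perm_counts,
        "perm_crit": int(crit),
        "exceeds_permutations": n_sig > crit,
    }
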