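"""Inversion karyotyping and haplotype-frequency tracking.

Marker SNPs are selected from karyotyped training individuals by linkage to
the inversion (r^2 to the 0/1 karyotype over homozygotes) and then refined by
mutual linkage, mirroring the breakpoint-marker strategy used for
In(2L)t-style cosmopolitan inversions. A linear SVM on marker dosages calls
held-out individuals inverted (INV), standard (STD), or heterozygous (HET,
via a symmetric margin band around the two-class score midpoint).

Haplotype trajectories in pooled data are proxied by "anchor" SNPs —
significant association hits (BH FDR q < 0.05 within a window) plus their
strong-LD partners (r^2 > 0.6 within +/-0.2 Mb) — whose polarized allele
frequencies are averaged per sample and regressed on an environmental
covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MarkerPanel",
    "KaryotypeCall",
    "AnchorSet",
    "bh_qvalues",
    "select_markers",
    "train_karyotyper",
    "Karyotyper",
    "inversion_ld",
    "build_anchor_set",
    "haplotype_trajectory",
]


def _r2_vec(dosage, target):
    """Squared Pearson correlation of each dosage column against a vector."""
    X = np.asarray(dosage, dtype=float)
    y = np.asarray(target, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r2 = r**2
    r2[(sx == 0) | (sy == 0)] = np.nan
    return r2, r


@dataclass
class MarkerPanel:
    snp_index: np.ndarray  # indices into the genotype matrix, panel order
    r2_train: np.ndarray  # per-marker r^2 to karyotype in training data
    mutual_r2: np.ndarray  # panel x panel LD matrix


def select_markers(genotypes, labels=None, ld_min=0.99, mutual_r2=0.8, k=47):
    """Select an inversion-marker panel from labeled homozygotes.

    Keeps SNPs whose dosage r^2 to the 0/1 karyotype (computed over INV/STD
    homozygote training individuals) exceeds ``ld_min``, then ranks by mean
    mutual r^2 among those candidates and keeps the top ``k`` subject to mean
    mutual r^2 > ``mutual_r2``. Selection is invariant to SNP input order
    (position-sorted tie-breaks). Warns and returns all qualifiers when fewer
    than ``k`` remain.
    """
    labels = genotypes.karyotype_label if labels is None else np.asarray(labels)
    homo = np.isin(labels, ["INV", "STD"])
    if len(np.unique(labels[homo])) < 2:
        raise ValueError("need both INV and STD labeled homozygotes")
    y = (labels[homo] == "INV").astype(float)
    D = genotypes.dosage[homo].astype(float)
    r2, _ = _r2_vec(D, y)
    with np.errstate(invalid="ignore"):
        cand = np.flatnonzero(r2 > ld_min)
    if len(cand) == 0:
        warnings.warn("no SNPs exceed the karyotype-LD threshold; empty panel")
        return MarkerPanel(np.array([], int), np.array([]), np.zeros((0, 0)))
    # canonical (position) order makes float reductions independent of SNP
    # input order, so selection is order-invariant
    cand = cand[np.lexsort((genotypes.pos[cand], genotypes.chrom[cand]))]
    C = D[:, cand]
    Cc = C - C.mean(axis=0)
    denom = np.sqrt((Cc**2).sum(axis=0))
    denom[denom == 0] = np.nan
    R = (Cc.T @ Cc) / np.outer(denom, denom)
    R2 = R**2
    np.fill_diagonal(R2, np.nan)
    mean_mut = np.nanmean(R2, axis=1) if len(cand) > 1 else np.ones(1)
    qual = mean_mut > mutual_r2
    if qual.sum() < min(k, len(cand)):
        warnings.warn(
            f"only {int(qual.sum())} SNPs pass the mutual-LD threshold (requested {k})"
        )
    idx = np.flatnonzero(qual)
    # rank by mean mutual r^2 (desc), tie-break on genomic position for
    # input-order invariance
    order = sorted(
        idx, key=lambda i: (-mean_mut[i], genotypes.pos[cand[i]])
    )[:k]
    order = np.array(order, dtype=int)
    sel = cand[order]
    return MarkerPanel(
        snp_index=sel,
        r2_train=r2[sel],
        mutual_r2=R2[np.ix_(order, order)],
    )


@dataclass
class Karyotyper:
    """Linear-SVM karyotype caller with a HET margin band."""

    panel: MarkerPanel
    svm: object
    midpoint: float
    band: float
    inv_side: float  # sign of the INV class on the decision axis

    def call(self, genotypes):
        """Karyotype calls for all individuals of a genotype matrix.

        Returns a DataFrame ``individual, score, marker_dosage_mean, call``.
        """
        X = genotypes.dosage[:, self.panel.snp_index].astype(float)
        score = self.svm.decision_function(X)
        rel = (score - self.midpoint) * self.inv_side
        call = np.where(rel > self.band, "INV", np.where(rel < -self.band, "STD", "HET"))
        return pd.DataFrame(
            {
                "individual": genotypes.individuals,
                "score": score,
                "marker_dosage_mean": X.mean(axis=1),
                "call": call,
            }
        )


def train_karyotyper(panel, genotypes, labels=None, C=1.0):
    """Train the linear SVM on labeled homozygotes.

    The decision function on marker dosages separates INV from STD training
    individuals; the HET band is the midpoint of the two classes' mean
    training scores +/- a quarter of the inter-class score gap (half of the
    half-gap), so an individual heterozygous at every marker lands in HET.
    """
    from sklearn.svm import SVC

    labels = genotypes.karyotype_label if labels is None else np.asarray(labels)
    homo = np.isin(labels, ["INV", "STD"])
    y = labels[homo]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both homozygous classes")
    X = genotypes.dosage[np.flatnonzero(homo)][:, panel.snp_index].astype(float)
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    score = svm.decision_function(X)
    s_inv = score[y == "INV"].mean()
    s_std = score[y == "STD"].mean()
    midpoint = (s_inv + s_std) / 2.0
    band = abs(s_inv - s_std) / 4.0
    return Karyotyper(
        panel=panel,
        svm=svm,
        midpoint=midpoint,
        band=band,
        inv_side=1.0 if s_inv >= s_std else -1.0,
    )


def inversion_ld(genotypes, karyotype_dosage, window_size=100_000):
    """Per-SNP r^2 between dosage and inversion (karyotype) dosage.

    Returns ``(per_snp, windowed)``: per-SNP r^2 (NaN for monomorphic SNPs)
    and a DataFrame of window means at ``window_size`` for reporting.
    """
    r2, _ = _r2_vec(genotypes.dosage.astype(float), np.asarray(karyotype_dosage, float))
    rows = []
    for c in pd.unique(genotypes.chrom):
        on = genotypes.chrom == c
        pos = genotypes.pos[on]
        vals = r2[on]
        start = 0
        while start <= pos.max():
            m = (pos >= start) & (pos < start + window_size)
            if m.any():
                rows.append((c, start, start + window_size, float(np.nanmean(vals[m]))))
            start += window_size
    return r2, pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_r2"])


def bh_qvalues(p):
    """Benjamini-Hochberg step-up q-values (min over the tail of m*p/rank)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class AnchorSet:
    """Anchor + partner loci proxying a local haplotype."""

    window: tuple  # (chrom, start, end)
    anchor_index: np.ndarray
    partner_index: np.ndarray
    polarity: dict  # snp index -> +1 (alt allele rides the inversion) or -1

    @property
    def all_index(self):
        return np.concatenate([self.anchor_index, self.partner_index]).astype(int)


def build_anchor_set(
    glm_p,
    genotypes,
    karyotype_dosage,
    window,
    q_max=0.05,
    r2_min=0.6,
    pad=200_000,
):
    """Anchor loci (BH q < ``q_max`` within the window) plus LD partners.

    ``glm_p`` maps genotype-matrix SNP indices to association P-values (array
    aligned to ``genotypes``; NaN = untested). BH correction is applied over
    the window's tested SNPs only. Partners are SNPs within ``pad`` of an
    anchor with dosage r^2 > ``r2_min`` to it. Polarity is +1 when the SNP's
    alt allele is positively correlated with the inverted karyotype, else -1.
    """
    chrom, start, end = window
    in_win = (genotypes.chrom == chrom) & (genotypes.pos >= start) & (genotypes.pos < end)
    tested = in_win & np.isfinite(np.asarray(glm_p, float))
    widx = np.flatnonzero(tested)
    if len(widx) == 0:
        return AnchorSet(window, np.array([], int), np.array([], int), {})
    q = bh_qvalues(np.asarray(glm_p, float)[widx])
    anchors = widx[q < q_max]
    if len(anchors) == 0:
        return AnchorSet(window, np.array([], int), np.array([], int), {})
    D = genotypes.dosage.astype(float)
    partners = set()
    for a in anchors:
        near = np.flatnonzero(
            (genotypes.chrom == chrom)
            & (np.abs(genotypes.pos - genotypes.pos[a]) <= pad)
        )
        near = near[~np.isin(near, anchors)]
        if len(near) == 0:
            continue
        r2, _ = _r2_vec(D[:, near], D[:, a])
        partners.update(near[np.nan_to_num(r2) > r2_min].tolist())
    partner_index = np.array(sorted(partners), dtype=int)
    _, r_k = _r2_vec(
        D[:, np.concatenate([anchors, partner_index]).astype(int)],
        np.asarray(karyotype_dosage, float),
    )
    polarity = {}
    for i, s in enumerate(np.concatenate([anchors, partner_index]).astype(int)):
        polarity[int(s)] = 1 if (np.isnan(r_k[i]) or r_k[i] >= 0) else -1
    return AnchorSet(window, anchors, partner_index, polarity)


def haplotype_trajectory(afm, anchor_set, covariate, snp_map=None):
    """Mean polarized anchor-set allele frequency per sample + regression.

    ``snp_map`` translates genotype-matrix SNP indices to AF-matrix row
    indices (default: identity). The per-sample trajectory is the unweighted
    mean of polarized anchor+partner frequencies (polarity -1 tracks the
    reference allele, i.e. 1 - AF). An ordinary least-squares fit of the
    trajectory on ``covariate`` is returned alongside; with a constant
    covariate or fewer than 3 samples the fit is flagged undefined.

    Returns a DataFrame (sample, mean_af) with ``.attrs['slope']``,
    ``['slope_se']``, ``['pvalue']`` (NaN when undefined).
    """
    idx = anchor_set.all_index
    if len(idx) == 0:
        raise ValueError("empty anchor set")
    rows = idx if snp_map is None else np.array([snp_map[int(i)] for i in idx])
    af = afm.af[rows]
    pol = np.array([anchor_set.polarity[int(i)] for i in idx])
    polarized = np.where(pol[:, None] == 1, af, 1.0 - af)
    traj = np.nanmean(polarized, axis=0)
    out = pd.DataFrame({"sample": afm.samples, "mean_af": traj})
    cov = np.asarray(covariate, dtype=float)
    ok = np.isfinite(traj) & np.isfinite(cov)
    if ok.sum() < 3 or np.std(cov[ok]) == 0:
        out.attrs.update(slope=np.nan, slope_se=np.nan, pvalue=np.nan, flagged=True)
        return out
    fit = sps.linregress(cov[ok], traj[ok])
    out.attrs.update(
        slope=fit.slope, slope_se=fit.stderr, pvalue=fit.pvalue, flagged=False
    )
    return out
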