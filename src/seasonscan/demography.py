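"""Boom-bust Wright-Fisher simulation and ABC inference of census sizes.

Overwintering insect populations cycle between a large growing-season census
size (N_Max) and a severe winter bottleneck (N_Min). The simulator runs a
single panmictic population of unlinked biallelic loci for ``n_generations``
(default 50, about three years at ~15 fly generations/season + winter), with
the population held at N_Max except during the bottleneck generations
(default 17-18 and 34-35) where it drops to N_Min. Each generation draws 2N
allele copies binomially from the parental frequency.

Loci are unlinked: none of the five ABC summary statistics (median within- and
between-year pool FST, and the R^2 of PC1/LD1/LD2 against simulated year) uses
linkage information, so dropping the chromosome-scale coalescent burn-in
preserves the inference target at a fraction of the cost.

Parameter estimation follows the Beaumont local-linear-regression ABC recipe:
z-score the summaries, accept the ``tolerance`` fraction of simulations
closest to the observed vector in Euclidean distance, then regress the (log)
parameters of the accepted draws on their summary deviations with an
Epanechnikov kernel and shift each draw to the fitted value at the observed
summaries. The derived effective population size is the harmonic mean of the
census schedule, N_e = G / sum_g(1/N_g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AlleleFrequencyMatrix
from .poolseq import dapc, pca_ordinate, pool_fst

__all__ = [
    "SimParams",
    "SimTrajectory",
    "SummaryStats",
    "AbcPosterior",
    "default_schedule",
    "harmonic_ne",
    "simulate_boom_bust",
    "emulate_poolseq",
    "default_sample_plan",
    "sim_summaries",
    "draw_prior",
    "run_abc_simulations",
    "abc_loclinear",
    "abc_leave_one_out",
]

SUMMARY_NAMES = ["fst_within", "fst_between", "r2_pc1", "r2_ld1", "r2_ld2"]


@dataclass
class SimParams:
    """Boom-bust simulation parameters."""

    n_max: float
    n_min: float
    n_generations: int = 50
    bust_generations: tuple = (17, 18, 34, 35)
    n_snps: int = 1000
    theta_pi: float = 0.001
    pool_n: int = 50
    coverage: float = 60.0

    def __post_init__(self):
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= N_Min <= N_Max")
        for g in self.bust_generations:
            if not (1 <= g <= self.n_generations):
                raise ValueError("bust generations must lie in [1, n_generations]")


@dataclass
class SimTrajectory:
    """Latent per-generation allele frequencies plus the census schedule.

    ``af`` has shape (n_generations + 1, n_snps); row 0 is the initial state.
    """

    af: np.ndarray
    census: np.ndarray
    params: SimParams


def default_schedule(params: SimParams):
    """Census size per generation 1..G (N_Max except at bust generations)."""
    census = np.full(params.n_generations, float(params.n_max))
    for g in params.bust_generations:
        census[g - 1] = float(params.n_min)
    return census


def harmonic_ne(census):
    """Harmonic mean of a census schedule: G / sum(1/N_g)."""
    census = np.asarray(census, dtype=float)
    return len(census) / np.sum(1.0 / census)


def _neutral_spectrum(n_snps, n_max, rng):
    """Initial frequencies from the neutral SFS (density ~ 1/x) truncated
    below at 1/(2*N_Max), with random allele labeling (fold symmetry)."""
    a = 1.0 / (2.0 * n_max)
    b = 1.0 - a
    u = rng.uniform(size=n_snps)
    p = a * (b / a) ** u  # inverse CDF of 1/x on [a, b]
    flip = rng.uniform(size=n_snps) < 0.5
    p[flip] = 1.0 - p[flip]
    return p


def simulate_boom_bust(params: SimParams, seed=None, init_af=None):
    """Forward Wright-Fisher simulation under the boom-bust schedule.

    ``init_af`` overrides the neutral-spectrum initial frequencies (useful for
    controlled drift experiments). Fixed loci stay fixed.
    """
    rng = np.random.default_rng(seed)
    if init_af is None:
        p = _neutral_spectrum(params.n_snps, params.n_max, rng)
    else:
        p = np.broadcast_to(np.asarray(init_af, dtype=float), (params.n_snps,)).copy()
    census = default_schedule(params)
    af = np.empty((params.n_generations + 1, params.n_snps))
    af[0] = p
    for g, n in enumerate(census, start=1):
        two_n = int(round(2 * n))
        counts = rng.binomial(two_n, af[g - 1])
        af[g] = counts / two_n
    return SimTrajectory(af=af, census=census, params=params)


def emulate_poolseq(traj: SimTrajectory, sample_generations, pool_n=None, coverage=None, seed=None):
    """Pool-seq emulation of selected generations of a trajectory.

    Per sampled generation: draw 2*pool_n chromosomes binomially from the
    latent frequency, then draw reads with depth ~ Poisson(coverage) and the
    read-level alt count binomial in the sampled chromosome frequency.
    Returns an :class:`AlleleFrequencyMatrix` (one sample per generation,
    named ``g<generation>``; AF is NaN where depth lands on 0).
    """
    pool_n = traj.params.pool_n if pool_n is None else pool_n
    coverage = traj.params.coverage if coverage is None else coverage
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    gens = list(sample_generations)
    for g in gens:
        if not (0 <= g <= traj.params.n_generations):
            raise ValueError(f"generation {g} not in trajectory")
    n_snps = traj.af.shape[1]
    two_n = 2 * pool_n
    af = np.empty((n_snps, len(gens)))
    depth = np.empty((n_snps, len(gens)))
    for j, g in enumerate(gens):
        chrom_freq = rng.binomial(two_n, traj.af[g]) / two_n
        d = rng.poisson(coverage, size=n_snps)
        reads = rng.binomial(d, chrom_freq)
        with np.errstate(invalid="ignore", divide="ignore"):
            af[:, j] = np.where(d > 0, reads / np.maximum(d, 1), np.nan)
        depth[:, j] = d
    snps = pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(1, n_snps + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    return AlleleFrequencyMatrix(
        snps=snps,
        samples=[f"g{g}" for g in gens],
        af=af,
        depth=depth,
        n_chrs=np.full(len(gens), float(two_n)),
    )


def default_sample_plan(params: SimParams, per_year=5):
    """Sampled generations and year labels mirroring a three-season design.

    Years are the inter-bottleneck epochs (1-16, 19-33, 36-50 under the
    default schedule), with ``per_year`` evenly spaced samples per year.
    """
    busts = sorted(params.bust_generations)
    # contiguous bust runs split the timeline into years
    epochs = []
    start = 1
    i = 0
    while i < len(busts):
        j = i
        while j + 1 < len(busts) and busts[j + 1] == busts[j] + 1:
            j += 1
        if busts[i] - 1 >= start:
            epochs.append((start, busts[i] - 1))
        start = busts[j] + 1
        i = j + 1
    if start <= params.n_generations:
        epochs.append((start, params.n_generations))
    gens, years = [], []
    for y, (a, b) in enumerate(epochs, start=1):
        pts = np.unique(np.linspace(a, b, per_year).round().astype(int))
        gens.extend(pts.tolist())
        years.extend([y] * len(pts))
    return gens, np.array(years)


@dataclass
class SummaryStats:
    """The five ABC summary statistics."""

    fst_within: float
    fst_between: float
    r2_pc1: float
    r2_ld1: float
    r2_ld2: float

    def to_array(self):
        return np.array([getattr(self, k) for k in SUMMARY_NAMES])


def _r2(x, y):
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def sim_summaries(afm: AlleleFrequencyMatrix, year_labels):
    """Compute the five summaries from a pool-seq matrix with year labels."""
    years = np.asarray(year_labels)
    uniq = np.unique(years)
    if len(uniq) < 2:
        raise ValueError("need samples from at least 2 years")
    within, between = [], []
    for i in range(afm.n_samples):
        for j in range(i + 1, afm.n_samples):
            _, gw = pool_fst(afm, (i, j))
            (within if years[i] == years[j] else between).append(gw)
    pcs = pca_ordinate(afm, n_pcs=2)
    r2_pc1 = _r2(pcs["PC1"].to_numpy(), years.astype(float))
    lds = dapc(afm, years)
    r2_ld1 = _r2(lds["LD1"].to_numpy(), years.astype(float))
    if "LD2" in lds.columns:
        r2_ld2 = _r2(lds["LD2"].to_numpy(), years.astype(float))
    else:
        r2_ld2 = 0.0
    return SummaryStats(
        fst_within=float(np.median(within)) if within else np.nan,
        fst_between=float(np.median(between)),
        r2_pc1=r2_pc1,
        r2_ld1=r2_ld1,
        r2_ld2=r2_ld2,
    )


def draw_prior(n, seed=None, n_max_range=(1e3, 1e5), n_min_range=(10.0, 1e4)):
    """Joint log-uniform prior on (N_Max, N_Min) with N_Min <= N_Max enforced
    by rejection."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        nmax = 10 ** rng.uniform(np.log10(n_max_range[0]), np.log10(n_max_range[1]), m)
        nmin = 10 ** rng.uniform(np.log10(n_min_range[0]), np.log10(n_min_range[1]), m)
        ok = nmin <= nmax
        k = int(ok.sum())
        out[filled : filled + k, 0] = nmax[ok]
        out[filled : filled + k, 1] = nmin[ok]
        filled += k
    return pd.DataFrame(out, columns=["n_max", "n_min"])


def run_abc_simulations(
    n_sims,
    seed=None,
    n_snps=400,
    per_year=5,
    n_generations=50,
    pool_n=50,
    coverage=60.0,
    prior_kwargs=None,
):
    """Draw parameters from the prior, simulate, and summarize.

    Returns ``(params, stats)`` DataFrames (one row per simulation).
    """
    rng = np.random.default_rng(seed)
    prior = draw_prior(n_sims, seed=rng.integers(2**31), **(prior_kwargs or {}))
    rows = []
    for i in range(n_sims):
        p = SimParams(
            n_max=prior.iloc[i]["n_max"],
            n_min=prior.iloc[i]["n_min"],
            n_generations=n_generations,
            n_snps=n_snps,
            pool_n=pool_n,
            coverage=coverage,
        )
        traj = simulate_boom_bust(p, seed=rng.integers(2**31))
        gens, years = default_sample_plan(p, per_year=per_year)
        afm = emulate_poolseq(traj, gens, seed=rng.integers(2**31))
        s = sim_summaries(afm, years)
        rows.append(s.to_array())
    stats = pd.DataFrame(rows, columns=SUMMARY_NAMES)
    return prior, stats


@dataclass
class AbcPosterior:
    """Accepted draws (raw and regression-adjusted) plus interval summaries."""

    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    table: pd.DataFrame  # index: parameter; columns: median, lo, hi

    def median(self, param):
        return float(self.table.loc[param, "median"])


def _posterior_table(draws: pd.DataFrame, weights, level=0.975):
    lo_q, hi_q = 1 - level, level
    rows = {}
    for col in draws.columns:
        v = draws[col].to_numpy()
        rows[col] = {
            "median": _wquantile(v, weights, 0.5),
            "lo": _wquantile(v, weights, lo_q),
            "hi": _wquantile(v, weights, hi_q),
        }
    return pd.DataFrame(rows).T[["median", "lo", "hi"]]


def _wquantile(v, w, q):
    order = np.argsort(v)
    v, w = v[order], np.asarray(w, dtype=float)[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return float(np.quantile(v, q))
    cw = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(q, cw, v))


def abc_loclinear(
    observed,
    sim_params: pd.DataFrame,
    sim_stats: pd.DataFrame,
    tolerance=0.05,
    n_generations=50,
    bust_generations=(17, 18, 34, 35),
):
    """Local-linear-regression ABC for the boom-bust parameters.

    Parameters
    ----------
    observed : SummaryStats or array-like
        Observed summary vector (same column order as ``sim_stats``).
    sim_params, sim_stats : DataFrame
        One row per simulation: parameter draws and their summaries.
    tolerance : float
        Fraction of simulations to accept (Euclidean distance on z-scored
        summaries).

    Returns
    -------
    AbcPosterior
        Raw and adjusted accepted draws (columns ``n_max, n_min, ne``), the
        kernel weights, and a median/97.5%-interval table per parameter.
    """
    if len(sim_params) < 100:
        raise ValueError("need at least 100 simulations for ABC")
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must lie in (0, 1]")
    obs = observed.to_array() if isinstance(observed, SummaryStats) else np.asarray(observed, float)
    S = sim_stats.to_numpy(float)
    keep_cols = []
    for j, name in enumerate(sim_stats.columns):
        sd = np.nanstd(S[:, j])
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"summary '{name}' has zero variance; dropped")
        else:
            keep_cols.append(j)
    S = S[:, keep_cols]
    obs = obs[keep_cols]
    mean, sd = S.mean(axis=0), S.std(axis=0)
    Z = (S - mean) / sd
    z_obs = (obs - mean) / sd
    dist = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    n_acc = max(1, int(round(tolerance * len(sim_params))))
    order = np.argsort(dist, kind="stable")[:n_acc]
    d_acc = dist[order]
    d_max = d_acc.max()
    if d_max > 0:
        w = 1.0 - (d_acc / d_max) ** 2
        w = np.maximum(w, 1e-12)
    else:
        w = np.ones(n_acc)
    raw = sim_params.iloc[order][["n_max", "n_min"]].reset_index(drop=True).copy()
    theta = np.log(raw.to_numpy(float))
    X = Z[order]
    n_params_fit = X.shape[1] + 1
    if n_acc > n_params_fit + 1:
        # weighted local-linear regression: theta ~ 1 + (Z - z_obs), with the
        # standard heteroscedasticity correction (residuals rescaled by the
        # locally fitted residual SD so posterior spread at the observed
        # summaries is not shrunk by spread elsewhere in the accepted cloud)
        D = np.column_stack([np.ones(n_acc), X - z_obs])
        Wsqrt = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(Wsqrt * D, Wsqrt * theta, rcond=None)
        fitted = D @ coef
        resid = theta - fitted
        log_r2 = np.log(np.maximum(resid**2, 1e-300))
        gamma, *_ = np.linalg.lstsq(Wsqrt * D, Wsqrt * log_r2, rcond=None)
        sigma = np.exp((D @ gamma) / 2.0)
        sigma_obs = np.exp(gamma[0] / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(sigma > 0, sigma_obs / sigma, 1.0)
        adj = coef[0] + resid * scale
    else:
        adj = theta
    adjusted = pd.DataFrame(np.exp(adj), columns=["n_max", "n_min"])
    # joint prior bound: N_Min <= N_Max
    over = adjusted["n_min"] > adjusted["n_max"]
    adjusted.loc[over, "n_min"] = adjusted.loc[over, "n_max"]

    def add_ne(df):
        ne = []
        for _, r in df.iterrows():
            p = SimParams(
                n_max=max(r["n_max"], r["n_min"], 1.0),
                n_min=max(min(r["n_min"], r["n_max"]), 1.0),
                n_generations=n_generations,
                bust_generations=bust_generations,
            )
            ne.append(harmonic_ne(default_schedule(p)))
        df = df.copy()
        df["ne"] = ne
        return df

    raw = add_ne(raw)
    adjusted = add_ne(adjusted)
    table = _posterior_table(adjusted, w)
    return AbcPosterior(raw=raw, adjusted=adjusted, weights=w, table=table)


def abc_leave_one_out(observed, sim_params, sim_stats, tolerance=0.05, **kwargs):
    """Influence of each summary statistic on the posterior medians.

    Reruns :func:`abc_loclinear` dropping one summary at a time; reports the
    shift in posterior median per parameter relative to the full set.
    """
    if sim_stats.shape[1] < 3:
        raise ValueError("need at least 3 summaries for leave-one-out")
    obs = observed.to_array() if isinstance(observed, SummaryStats) else np.asarray(observed, float)
    full = abc_loclinear(obs, sim_params, sim_stats, tolerance, **kwargs)
    rows = []
    for j, name in enumerate(sim_stats.columns):
        cols = [c for c in sim_stats.columns if c != name]
        sub = abc_loclinear(
            np.delete(obs, j), sim_params, sim_stats[cols], tolerance, **kwargs
        )
        for param in ("n_max", "n_min", "ne"):
            rows.append(
                {
                    "dropped": name,
                    "param": param,
                    "median": sub.median(param),
                    "shift": sub.median(param) - full.median(param),
                }
            )
    return pd.DataFrame(rows)
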