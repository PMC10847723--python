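"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a multi-year orchard time series of
pooled *Drosophila* samples:

* daily weather with an annual temperature cycle, autocorrelated noise,
  rainfall, and relative humidity;
* latent allele-frequency drift under boom-bust demography (growing-season
  booms punctuated by overwintering bottlenecks);
* an inversion-like linkage block whose single latent haplotype frequency
  responds to a named environmental covariate on the logit scale, with block
  SNPs tracking the block frequency at tunable weight (hence tunable LD);
* two-stage pool-seq observation noise — binomial sampling of pooled
  chromosomes, then binomial read sampling at Poisson-distributed depth;
* individually sequenced genotypes with inversion karyotypes and marker SNPs
  in tunable LD to the karyotype; and
* GWAS summary statistics with a planted fraction of environment-responsive
  SNPs among the top hits.

Every output carries truth labels so downstream power and calibration are
testable without external data. None of this simulates sequence reads,
diploid selection, or migration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import AlleleFrequencyMatrix
from .demography import SimParams, simulate_boom_bust

__all__ = [
    "gen_weather",
    "SyntheticStudy",
    "gen_study",
    "GenotypeMatrix",
    "gen_individuals",
    "gen_gwas_summary",
    "write_study",
    "write_weather_tsv",
    "read_weather_tsv",
    "write_genotypes_vcf",
]


def gen_weather(
    n_days,
    seed=None,
    seasonal_amplitude=13.0,
    mean_temp=19.0,
    noise_sd=3.0,
    diurnal_range=8.0,
    ar_phi=0.7,
    start="2016-01-01",
):
    """Daily weather series: sinusoidal annual cycle plus AR(1) noise.

    Daily maximum temperature peaks in mid-July; under the defaults a
    two-year series contains days above 32 C and days below 5 C so that
    threshold covariates (proportion of hot/cold days) are non-degenerate.

    Returns a DataFrame with columns ``date, tmax, tmin, precip, rh``.
    """
    if n_days < 120:
        raise ValueError("series too short for 0-90 day windows")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    cycle = mean_temp + seasonal_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.25)
    eps = np.empty(n_days)
    innov = rng.normal(0.0, 1.0, n_days)
    eps[0] = innov[0]
    for t in range(1, n_days):
        eps[t] = ar_phi * eps[t - 1] + np.sqrt(1 - ar_phi**2) * innov[t]
    tmax = cycle + diurnal_range / 2.0 + noise_sd * eps
    tmin = tmax - diurnal_range
    wet = rng.uniform(size=n_days) < 0.35
    precip = np.where(wet, rng.gamma(0.8, 8.0, n_days), 0.0)
    rh = 65.0 + 15.0 * np.sin(2 * np.pi * (doy - 280) / 365.25) + 5.0 * rng.normal(size=n_days)
    rh = np.clip(rh, 0.0, 100.0)
    return pd.DataFrame(
        {"date": dates, "tmax": tmax, "tmin": tmin, "precip": precip, "rh": rh}
    )


@dataclass
class SyntheticStudy:
    """A full synthetic pool-seq study with ground truth."""

    afm: AlleleFrequencyMatrix
    meta: pd.DataFrame
    weather: pd.DataFrame
    truth: pd.DataFrame
    karyo_freq_by_sample: np.ndarray
    latent_af: np.ndarray  # SNP x sample latent frequencies (pre-noise)
    planted_variable: str


def _snp_positions(n_snps, rng, chroms=("2L", "2R"), mean_spacing=2000):
    """Strictly increasing jittered positions split across chromosomes."""
    per = np.full(len(chroms), n_snps // len(chroms))
    per[: n_snps % len(chroms)] += 1
    chrom_col, pos_col = [], []
    for c, k in zip(chroms, per):
        gaps = rng.integers(mean_spacing // 4, mean_spacing * 2, size=k)
        pos = np.cumsum(gaps) + 10_000
        chrom_col.extend([c] * k)
        pos_col.extend(pos.tolist())
    return np.array(chrom_col), np.array(pos_col)


def gen_study(
    n_snps=2000,
    n_samples_per_year=8,
    n_years=3,
    n_planted=60,
    pool_size=100,
    coverage=60.0,
    seed=None,
    effect_size=1.0,
    planted_variable="temp_max_0-15d",
    block_n_snps=None,
    r_block=0.9,
    block_chrom="2L",
    block_span=(2_000_000, 2_500_000),
    n_max=20_000,
    n_min=300,
    init_spectrum="common",
    gens_per_year=15,
    first_collection_doy=166,
    collection_interval_days=14,
):
    """Generate a complete synthetic seasonal study.

    Latent neutral frequencies drift along a boom-bust trajectory (N_Max in
    season, N_Min overwinter). An inversion-like block of ``block_n_snps``
    SNPs (default: the planted count) on ``block_chrom`` shares a single
    latent haplotype frequency whose logit responds to the standardized
    ``planted_variable`` covariate with slope ``effect_size``; block SNPs mix
    that haplotype frequency with their own neutral background at weight
    ``r_block``. Planted SNPs live inside the block. Observed frequencies add
    two-stage pool-seq noise (``pool_size`` chromosomes, then reads at mean
    ``coverage``).
    """
    if n_planted > n_snps:
        raise ValueError("n_planted cannot exceed n_snps")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)

    # --- sampling calendar -------------------------------------------------
    start_year = 2016
    dates, years = [], []
    for y in range(n_years):
        base = pd.Timestamp(f"{start_year + y}-01-01") + pd.Timedelta(
            days=first_collection_doy - 1
        )
        for k in range(n_samples_per_year):
            dates.append(base + pd.Timedelta(days=collection_interval_days * k))
            years.append(start_year + y)
    dates = pd.DatetimeIndex(dates)
    weather_start = dates.min() - pd.Timedelta(days=120)
    n_days = (dates.max() - weather_start).days + 30
    weather = gen_weather(n_days, seed=rng.integers(2**31), start=weather_start)

    # --- environmental covariate driving the planted response --------------
    from .envglm import build_env_covariates, parse_covariate_id

    meta = pd.DataFrame(
        {
            "sample": [f"S{y}_{i % n_samples_per_year:02d}" for i, y in enumerate(years)],
            "locality": "orchard1",
            "date": dates,
            "year": years,
            "cluster": "cluster1",
        }
    )
    parse_covariate_id(planted_variable)  # validates the id names a real covariate
    cov = build_env_covariates(weather, meta)
    if planted_variable not in cov.columns:
        raise ValueError(f"planted variable {planted_variable!r} not in covariate grid")
    gamma = cov[planted_variable].to_numpy(float)
    z_gamma = (gamma - gamma.mean()) / gamma.std()

    # --- latent drift trajectories -----------------------------------------
    n_samples = len(meta)
    bust = []
    g = 0
    for y in range(n_years - 1):
        g += gens_per_year
        bust.extend([g + 1, g + 2])
        g += 2
    n_generations = g + gens_per_year
    params = SimParams(
        n_max=n_max,
        n_min=n_min,
        n_generations=n_generations,
        bust_generations=tuple(bust) if bust else (1,),
        n_snps=n_snps,
    )
    # initial spectrum: 'common' mimics a MAF-filtered analysis panel
    # (uniform folded frequencies); 'neutral' uses the simulator's 1/x
    # spectrum including rare variants.
    if init_spectrum == "common":
        init_af = rng.uniform(0.05, 0.95, size=n_snps)
    elif init_spectrum == "neutral":
        init_af = None
    else:
        raise ValueError(f"unknown init_spectrum {init_spectrum!r}")
    traj = simulate_boom_bust(params, seed=rng.integers(2**31), init_af=init_af)
    # inversion-like haplotype: a balanced polymorphism held near intermediate
    # frequency, drifting under the same schedule
    block_params = SimParams(
        n_max=n_max,
        n_min=n_min,
        n_generations=n_generations,
        bust_generations=tuple(bust) if bust else (1,),
        n_snps=1,
    )
    block_traj = simulate_boom_bust(
        block_params, seed=rng.integers(2**31), init_af=0.5
    )
    season_len = collection_interval_days * (n_samples_per_year - 1) + 1
    sample_gens = []
    for i in range(n_samples):
        y = i // n_samples_per_year
        k = i % n_samples_per_year
        boom_start = y * (gens_per_year + 2) + 1
        offset = int(round((collection_interval_days * k) / season_len * (gens_per_year - 1)))
        sample_gens.append(boom_start + offset)
    sample_gens = np.array(sample_gens)
    latent = traj.af[sample_gens, :].T.copy()  # SNP x sample
    # keep latent frequencies away from the boundary so logit shifts are defined
    eps = 1e-4
    latent = np.clip(latent, eps, 1 - eps)

    # --- inversion block ----------------------------------------------------
    block_n = n_planted if block_n_snps is None else block_n_snps
    if block_n > n_snps:
        raise ValueError("more inversion-block SNPs than SNPs")
    chrom, pos = _snp_positions(n_snps, rng)
    in_span = (chrom == block_chrom) & (pos >= block_span[0]) & (pos <= block_span[1])
    block_idx = np.flatnonzero(in_span)[:block_n]
    if len(block_idx) < block_n:
        # span too sparse at this study size: use a centered contiguous run
        # on the block chromosome instead
        on_chrom = np.flatnonzero(chrom == block_chrom)
        start = max(0, (len(on_chrom) - block_n) // 2)
        block_idx = on_chrom[start : start + block_n]
    block_drift = np.clip(block_traj.af[sample_gens, 0], eps, 1 - eps)
    block_freq = expit(logit(block_drift) + effect_size * z_gamma)
    latent[block_idx] = r_block * block_freq[None, :] + (1 - r_block) * latent[block_idx]

    # --- planted truth ------------------------------------------------------
    planted_idx = block_idx[:n_planted]
    if n_planted > len(block_idx):
        outside = np.setdiff1d(np.arange(n_snps), block_idx)
        extra = outside[: n_planted - len(block_idx)]
        latent[extra] = expit(logit(latent[extra]) + effect_size * z_gamma[None, :])
        planted_idx = np.concatenate([block_idx, extra])
    is_planted = np.zeros(n_snps, dtype=bool)
    is_planted[planted_idx] = True
    in_block = np.zeros(n_snps, dtype=bool)
    in_block[block_idx] = True
    truth = pd.DataFrame(
        {
            "snp": np.arange(n_snps),
            "chrom": chrom,
            "pos": pos,
            "is_planted": is_planted,
            "true_env_variable": np.where(is_planted, planted_variable, ""),
            "effect_size": np.where(is_planted, effect_size, 0.0),
            "in_inversion_block": in_block,
        }
    )

    # --- pool-seq observation noise ----------------------------------------
    chrom_freq = rng.binomial(int(pool_size), latent) / float(pool_size)
    depth = rng.poisson(coverage, size=latent.shape).astype(float)
    reads = rng.binomial(depth.astype(int), chrom_freq)
    with np.errstate(invalid="ignore", divide="ignore"):
        af_obs = np.where(depth > 0, reads / np.maximum(depth, 1.0), np.nan)

    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"})
    afm = AlleleFrequencyMatrix(
        snps=snps,
        samples=meta["sample"].tolist(),
        af=af_obs,
        depth=depth,
        n_chrs=np.full(n_samples, float(pool_size)),
    )
    return SyntheticStudy(
        afm=afm,
        meta=meta,
        weather=weather,
        truth=truth,
        karyo_freq_by_sample=block_freq,
        latent_af=latent,
        planted_variable=planted_variable,
    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosages with (training) karyotype labels."""

    dosage: np.ndarray  # (n_individuals, n_snps) in {0, 1, 2}
    chrom: np.ndarray
    pos: np.ndarray
    individuals: list
    karyotype_label: np.ndarray  # 'INV'/'STD'/'HET' or '' (unlabeled)
    is_marker: np.ndarray
    true_karyo_dosage: np.ndarray  # ground truth, all individuals

    @property
    def n_individuals(self):
        return self.dosage.shape[0]

    @property
    def n_snps(self):
        return self.dosage.shape[1]


def gen_individuals(
    n_train=80,
    n_test=120,
    n_markers=47,
    marker_ld=0.99,
    seed=None,
    inv_freq=0.45,
    n_other_snps=200,
    train_homozygous_only=True,
):
    """Individual genotypes with an inversion karyotype and marker panel.

    Each individual carries two haplotypes whose inversion allele is Bernoulli
    (``inv_freq``). A marker SNP copies the haplotype's inversion allele with
    probability sqrt(``marker_ld``) and otherwise draws a fresh allele at the
    same frequency, which yields dosage-level r^2 equal to ``marker_ld``.
    Non-marker SNPs are independent. Labels (INV/STD/HET from the true
    karyotype dosage) are attached to training individuals only; with
    ``train_homozygous_only`` heterozygous would-be training individuals are
    left unlabeled, mirroring training panels of karyotyped inbred lines.
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    if not (0 < marker_ld <= 1):
        raise ValueError("marker_ld must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_ind = n_train + n_test
    hap_inv = rng.uniform(size=(n_ind, 2)) < inv_freq  # inversion allele per haplotype
    karyo_dosage = hap_inv.sum(axis=1)
    a = np.sqrt(marker_ld)
    copy = rng.uniform(size=(n_ind, 2, n_markers)) < a
    fresh = rng.uniform(size=(n_ind, 2, n_markers)) < inv_freq
    marker_hap = np.where(copy, hap_inv[:, :, None], fresh)
    marker_dosage = marker_hap.sum(axis=1)
    other_freq = rng.uniform(0.1, 0.9, size=n_other_snps)
    other_dosage = rng.binomial(2, other_freq, size=(n_ind, n_other_snps))
    dosage = np.concatenate([marker_dosage, other_dosage], axis=1).astype(np.int8)
    n_snps = n_markers + n_other_snps
    pos = np.sort(rng.choice(np.arange(2_000_000, 12_000_000), size=n_snps, replace=False))
    is_marker = np.zeros(n_snps, dtype=bool)
    marker_slots = np.sort(rng.choice(n_snps, size=n_markers, replace=False))
    # place marker columns at their genomic slots
    full = np.empty_like(dosage)
    full[:, marker_slots] = dosage[:, :n_markers]
    other_slots = np.setdiff1d(np.arange(n_snps), marker_slots)
    full[:, other_slots] = dosage[:, n_markers:]
    is_marker[marker_slots] = True
    label_names = np.array(["STD", "HET", "INV"])
    labels = np.full(n_ind, "", dtype=object)
    train_idx = np.arange(n_train)
    lab = label_names[karyo_dosage[train_idx]]
    if train_homozygous_only:
        lab = np.where(lab == "HET", "", lab)
    labels[train_idx] = lab
    return GenotypeMatrix(
        dosage=full,
        chrom=np.array(["2L"] * n_snps),
        pos=pos,
        individuals=[f"ind{i:04d}" for i in range(n_ind)],
        karyotype_label=labels.astype(str),
        is_marker=is_marker,
        true_karyo_dosage=karyo_dosage.astype(int),
    )


def gen_gwas_summary(
    truth,
    overlap_frac,
    seed=None,
    phenotypes=("pheno1",),
    categories=None,
    top_p_range=(1e-8, 1e-4),
):
    """GWAS summary statistics with planted overlap.

    A fraction ``overlap_frac`` of planted environment-responsive SNPs is
    assigned small GWAS P-values with effect signs aligned to the planted
    environmental slope; the rest are null (uniform P, centered small beta).
    Returns one row per SNP x phenotype: ``snp, phenotype, beta, p, category``.
    """
    if not (0 <= overlap_frac <= 1):
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cats = ["Behavior", "Life-History", "Morphology", "Stress-resistance"]
    if categories is None:
        categories = [cats[i % len(cats)] for i in range(len(phenotypes))]
    planted = truth.index[truth["is_planted"]].to_numpy()
    n_snps = len(truth)
    frames = []
    for pheno, cat in zip(phenotypes, categories):
        beta = rng.normal(0.0, 0.1, n_snps)
        p = rng.uniform(size=n_snps)
        k = int(round(overlap_frac * len(planted)))
        hit = rng.choice(planted, size=k, replace=False) if k else np.array([], dtype=int)
        if k:
            lo, hi = np.log10(top_p_range[0]), np.log10(top_p_range[1])
            p[hit] = 10 ** rng.uniform(lo, hi, k)
            sign = np.sign(truth.loc[hit, "effect_size"].to_numpy())
            sign[sign == 0] = 1.0
            beta[hit] = sign * np.abs(rng.normal(0.3, 0.1, k))
        frames.append(
            pd.DataFrame(
                {
                    "snp": np.arange(n_snps),
                    "phenotype": pheno,
                    "beta": beta,
                    "p": p,
                    "category": cat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------ writers
def write_weather_tsv(weather, path):
    out = weather.rename(
        columns={"tmax": "TMAX", "tmin": "TMIN", "precip": "PRECIP", "rh": "RH"}
    )
    out = out.assign(date=pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d"))
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return Path(path)


def read_weather_tsv(path):
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"TMAX": "tmax", "TMIN": "tmin", "PRECIP": "precip", "RH": "rh"})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_study(study: SyntheticStudy, outdir):
    """Write af.tsv, meta.tsv, weather.tsv, truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.afm.to_tsv(outdir / "af.tsv")
    meta = study.meta.assign(date=study.meta["date"].dt.strftime("%Y-%m-%d"))
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    write_weather_tsv(study.weather, outdir / "weather.tsv")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir


def write_genotypes_vcf(gm: GenotypeMatrix, path):
    """Write dosages as an unphased GT-only VCF (1-based positions)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j in range(gm.n_snps):
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return Path(path)
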