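"""End-to-end orchestration: synthetic study -> GLM -> windows -> karyotype
-> cross-model, with deterministic seeding and a provenance manifest.

Every stage writes plain TSV/JSON into the run directory so intermediate
results are diffable; a manifest records the config, derived stage seeds,
and SHA-256 hashes of inputs and outputs. Identical configs reproduce
identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import read_af_table, read_metadata
from .crossmodel import directionality, fet_enrichment, top_set
from .envglm import build_env_covariates, relative_rate, run_glm_battery
from .karyotype import select_markers, train_karyotyper
from .poolseq import filter_snps
from .synth import (
    gen_gwas_summary,
    gen_individuals,
    gen_study,
    read_weather_tsv,
    write_study,
)
from .windows import (
    assign_windows,
    empirical_threshold,
    make_windows,
    rank_normalize,
    signal_enrichment,
    windows_of_interest,
    wza,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Pipeline configuration; serializes round-trip to YAML."""

    seed: int = 0
    out_dir: str = "seasonscan_run"
    # inputs: paths to af/meta/weather TSVs; None -> synthesize
    af_path: str | None = None
    meta_path: str | None = None
    weather_path: str | None = None
    synth: dict = field(
        default_factory=lambda: {
            "n_snps": 2000,
            "n_samples_per_year": 8,
            "n_years": 3,
            "n_planted": 60,
            "effect_size": 1.0,
        }
    )
    maf_min: float = 0.01
    mean_neff_min: float = 28.0
    design: str = "year"
    n_perm: int = 20
    top_q: float = 0.05
    window_size: int = 100_000
    window_step: int = 50_000
    gwas_overlap: float = 0.5

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return Path(path)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(paths):
    """Format/consistency checks on a (af, meta, weather) input bundle.

    ``paths``: dict with any of keys ``af, meta, weather``. Returns a list of
    failure strings (empty = valid); never raises on content problems.
    """
    failures = []
    afm = meta = weather = None
    if "af" in paths:
        try:
            afm = read_af_table(paths["af"])
            bad = np.flatnonzero(np.nanmax(afm.af, axis=1) > 1 + 1e-9)
            for i in bad[:5]:
                failures.append(f"af: frequency > 1 at SNP row {i}")
        except Exception as exc:
            failures.append(f"af: {exc}")
    if "meta" in paths:
        try:
            meta = read_metadata(paths["meta"])
        except Exception as exc:
            failures.append(f"meta: {exc}")
    if afm is not None and meta is not None:
        missing = set(afm.samples) - set(meta["sample"])
        if missing:
            failures.append(f"join: samples without metadata: {sorted(missing)[:5]}")
    if "weather" in paths:
        try:
            weather = read_weather_tsv(paths["weather"])
            if (weather["tmax"] < weather["tmin"]).any():
                failures.append("weather: tmax < tmin on some days")
            gaps = weather["date"].diff().dt.days.iloc[1:]
            if (gaps != 1).any():
                failures.append("weather: dates not consecutive")
        except Exception as exc:
            failures.append(f"weather: {exc}")
    if weather is not None and meta is not None:
        lo = meta["date"].min() - pd.Timedelta(days=90)
        if weather["date"].min() > lo:
            failures.append("weather: does not cover 90 days before earliest sample")
    return failures


def run_pipeline(config: RunConfig):
    """Run all stages; returns the run directory path.

    Stage order: synth (or load) -> validate -> filter -> covariates -> GLM
    battery with permutations -> model enrichment -> window scans with
    permutation thresholds -> karyotyper training -> GWAS cross-model
    statistics -> manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = np.random.default_rng(config.seed)
    seeds = {k: int(base.integers(2**31)) for k in ("synth", "glm", "indiv", "gwas")}

    # --- inputs -------------------------------------------------------------
    truth = None
    if config.af_path:
        afm = read_af_table(config.af_path)
        meta = read_metadata(config.meta_path)
        weather = read_weather_tsv(config.weather_path)
        input_paths = {
            "af": config.af_path,
            "meta": config.meta_path,
            "weather": config.weather_path,
        }
    else:
        study = gen_study(seed=seeds["synth"], **config.synth)
        write_study(study, out / "inputs")
        afm, meta, weather, truth = study.afm, study.meta, study.weather, study.truth
        input_paths = {
            "af": out / "inputs/af.tsv",
            "meta": out / "inputs/meta.tsv",
            "weather": out / "inputs/weather.tsv",
        }
    failures = validate_inputs(input_paths)
    if failures:
        raise ValueError("input validation failed: " + "; ".join(failures))

    # --- filter + covariates ------------------------------------------------
    afm, report = filter_snps(afm, config.maf_min, config.mean_neff_min)
    meta = meta.set_index("sample").loc[afm.samples].reset_index()
    cov = build_env_covariates(weather, meta)

    # --- GLM battery ---------------------------------------------------------
    battery0 = run_glm_battery(afm, meta, cov, design=config.design, n_perm=0)
    env_best = pd.Series(
        [b for b in battery0.real_best if b not in (None, "null", "time")]
    )
    focal = env_best.mode().iat[0] if len(env_best) else cov.columns[0]
    battery = run_glm_battery(
        afm,
        meta,
        cov,
        design=config.design,
        n_perm=config.n_perm,
        seed=seeds["glm"],
        track_perm_p_for=[focal],
    )
    battery.fits.to_csv(out / "glm_fits.tsv", sep="\t", index=False)
    if truth is not None:
        kept = truth.merge(
            afm.snps[["chrom", "pos"]], on=["chrom", "pos"], how="right"
        )
        regions = np.where(kept["in_inversion_block"].fillna(False), "inv", "outside")
    else:
        regions = afm.snps["chrom"].to_numpy()
    rr = relative_rate(battery.real_best, battery.perm_best, battery.model_ids, regions)
    rr.to_csv(out / "model_enrichment.tsv", sep="\t", index=False)

    # --- window scans --------------------------------------------------------
    chrom = afm.snps["chrom"].to_numpy()
    pos = afm.snps["pos"].to_numpy()
    p_real = battery.env_lrt_p[focal].to_numpy()
    ranked = rank_normalize(p_real, chrom, pos)
    win = make_windows(chrom, pos, config.window_size, config.window_step)
    members = assign_windows(win, chrom, pos)
    enr = signal_enrichment(ranked, win, members, top_q=config.top_q)
    maf = afm.folded_maf()
    wz = wza(ranked, win, members, maf=maf)
    enr["wza_z"] = wz["wza_z"]
    perm_p = battery.perm_env_lrt_p[focal]
    perm_scores = []
    for k in range(perm_p.shape[0]):
        rk = rank_normalize(perm_p[k], chrom, pos)
        pe = signal_enrichment(rk, win, members, top_q=config.top_q)
        perm_scores.append(-np.log10(np.maximum(pe["binom_p"].to_numpy(), 1e-300)))
    perm_scores = np.array(perm_scores)
    real_score = -np.log10(np.maximum(enr["binom_p"].to_numpy(), 1e-300))
    crit = empirical_threshold(perm_scores, level=0.99)
    enr["score"] = real_score
    enr["crit_99"] = crit
    enr.to_csv(out / "window_scan.tsv", sep="\t", index=False)
    woi = windows_of_interest(win, real_score, crit)
    woi.to_csv(out / "windows_of_interest.tsv", sep="\t", index=False)

    # --- karyotyper ----------------------------------------------------------
    gm = gen_individuals(seed=seeds["indiv"])
    panel = select_markers(gm)
    karyo = train_karyotyper(panel, gm)
    calls = karyo.call(gm)
    calls.to_csv(out / "karyotype_calls.tsv", sep="\t", index=False)

    # --- cross-model ---------------------------------------------------------
    cross = {}
    if truth is not None:
        kept_truth = truth.merge(afm.snps[["chrom", "pos"]], on=["chrom", "pos"])
        gwas = gen_gwas_summary(kept_truth, config.gwas_overlap, seed=seeds["gwas"])
        gwas.to_csv(out / "gwas_summary.tsv", sep="\t", index=False)
        glm_top = top_set(p_real, q=config.top_q, chrom=chrom, pos=pos)
        gwas_top = top_set(gwas["p"].to_numpy(), q=config.top_q, chrom=chrom, pos=pos)
        res = fet_enrichment(glm_top, gwas_top)
        beta2 = battery.fits.loc[battery.fits["model"] == focal, "beta2"].to_numpy()
        dscore, n_d = directionality(
            beta2, gwas["beta"].to_numpy(), glm_top, gwas_top
        )
        cross = {
            "focal_model": focal,
            "fet_odds_ratio": res.odds_ratio,
            "fet_p": res.p_value,
            "directionality_pct": dscore,
            "directionality_n": n_d,
        }
        with open(out / "crossmodel.json", "w") as fh:
            json.dump(cross, fh, indent=2)

    # --- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "focal_model": focal,
        "filter": {
            "samples_dropped": report.n_samples_dropped,
            "snps_dropped": report.n_snps_dropped,
        },
        "input_hashes": {k: _sha256(v) for k, v in input_paths.items()},
        "output_hashes": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
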