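"""Cross-analysis enrichment and directionality: GLM vs GWAS.

Generates GWAS summary statistics with 50% planted overlap with the
environment-responsive SNPs, then measures (1) Fisher-exact enrichment of
joint top-5% membership and (2) the directionality score — the percent of
jointly significant SNPs whose effect signs agree (null expectation 50%).
"""

import numpy as np

import seasonscan as ss
from seasonscan.crossmodel import directionality, fet_enrichment, top_set
from seasonscan.envglm import build_env_covariates, run_glm_battery
from seasonscan.synth import gen_gwas_summary

study = ss.gen_study(n_snps=800, n_samples_per_year=8, n_planted=60, seed=13)
cov = build_env_covariates(study.weather, study.meta)
bat = run_glm_battery(study.afm, study.meta, cov[[study.planted_variable]])
glm_p = bat.env_lrt_p[study.planted_variable].to_numpy()
beta2 = bat.fits.loc[bat.fits["model"] == study.planted_variable, "beta2"].to_numpy()

gwas = gen_gwas_summary(study.truth, overlap_frac=0.5, seed=14)
chrom = study.afm.snps["chrom"].to_numpy()
pos = study.afm.snps["pos"].to_numpy()
glm_top = top_set(glm_p, chrom=chrom, pos=pos)
gwas_top = top_set(gwas["p"].to_numpy(), chrom=chrom, pos=pos)

res = fet_enrichment(glm_top, gwas_top)
print(f"joint top-5% overlap: {res.table[0, 0]} SNPs")
print(f"enrichment OR = {res.odds_ratio:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], one-sided FET p = {res.p_value:.2e}")

pct, n = directionality(beta2, gwas["beta"].to_numpy(), glm_top, gwas_top)
print(f"directionality = {pct:.1f}% over {n} jointly significant SNPs")
print("(100% or 0% = coordinated block-like change; 50% = no alignment)")
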