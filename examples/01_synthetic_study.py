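"""Generate a synthetic seasonal pool-seq study and inspect its structure.

Builds three years of biweekly pooled samples with boom-bust drift, a
responsive inversion-like block, and pool-seq noise, then prints the study's
shape and the planted truth. The block's latent haplotype frequency falls
when recent maximum temperatures rise (negative response mirrors an
overwintering-adapted haplotype).
"""

import numpy as np

import seasonscan as ss

study = ss.gen_study(
    n_snps=1000, n_samples_per_year=8, n_years=3, n_planted=60, seed=42
)

print(f"samples: {study.afm.n_samples}  SNPs: {study.afm.n_snps}")
print(f"mean effective coverage per sample: {study.afm.mean_neff().mean():.1f}")
print(f"planted SNPs: {study.truth['is_planted'].sum()} "
      f"(inversion block: {study.truth['in_inversion_block'].sum()})")
print(f"planted covariate: {study.planted_variable}")
print("block haplotype frequency by sample:")
print(np.round(study.karyo_freq_by_sample, 3))
# Each planted SNP's observed frequency tracks the block trajectory up to
# binomial pool+read noise; neutral SNPs only drift.
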