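"""Splicing-efficiency QTL scan with a conditional follow-up.

Simulates a 375-animal cohort with a causal dinucleotide variant (K232A-like)
whose K allele increases splicing efficiency at junction 8, scans 200 markers
in a 1 Mbp interval, then re-scans with the causal dosage as a covariate.
The causal marker should top the plain scan, and its LD proxies should lose
all signal in the conditional scan.
"""

import numpy as np
import pandas as pd

from junctionqtl.association import bonferroni_threshold, genotype_class_summary, scan
from junctionqtl.synthetic_data import (
    SimulationConfig,
    covariate_design,
    phenotypes_from_counts,
    simulate_covariates,
    simulate_genotypes,
    simulate_junction_counts,
    simulate_truth,
)

cfg = SimulationConfig(seed=2)  # study-anchored defaults: n=375, K freq 0.51
genotypes = simulate_genotypes(cfg)
covariates = simulate_covariates(cfg, genotypes)
truth = simulate_truth(cfg, genotypes, covariates)
pheno = phenotypes_from_counts(simulate_junction_counts(cfg, truth))

y = pd.Series(np.log(pheno["eff_8"].to_numpy()), index=genotypes.sample_ids)
X = covariate_design(covariates)

plain = scan(y, genotypes, covariates=X, focal="K232A")
print("Top 5 markers, splicing efficiency at junction 8 (log ratio):")
print(
    plain.sort_values("rank").head(5)[["marker", "pos", "beta", "p", "rank", "r2_with_focal"]]
    .to_string(index=False)
)

threshold = bonferroni_threshold(0.05, cfg.n_markers)
cond = scan(y, genotypes, covariates=X, condition_on="K232A")
n_sig_before = int((plain["p"] < threshold).sum())
n_sig_after = int((cond["p"].dropna() < threshold).sum())
print(f"\nBonferroni threshold (0.05 / {cfg.n_markers} markers): {threshold:.2e}")
print(f"significant markers before conditioning on the causal MNP: {n_sig_before}")
print(f"significant markers after conditioning:                    {n_sig_after}")

summary = genotype_class_summary(
    pheno["intronpct_8"].to_numpy(), genotypes.dosages_of("K232A")
)
print("\nIntron-8 read % by causal genotype (dosage of K allele):")
print(summary.round(3).to_string(index=False))
print("\nK-allele carriers retain less intron 8: higher splicing efficiency.")
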