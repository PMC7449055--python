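# Default cohort conditions for the synthetic generator: a lactating-cow
# mammary RNA-seq study design around the DGAT1 K232A dinucleotide MNP.
# Per-genotype triples are ordered (AA, AK, KK) by dosage of the K allele.
n_animals: 375
causal_allele_freq: 0.51        # K-allele frequency in the cohort
n_markers: 200
ld_decay: 0.03                  # per-marker-step haplotype flip probability
chrom: chr14
region_span: 1000000            # 1 Mbp interval centred on the causal MNP

# percentage of gene reads touching the intron, per genotype class
intron_pct_by_genotype:
  8: [1.94, 1.53, 1.16]
  2: [1.90, 1.45, 1.10]
  7: [1.80, 1.45, 1.15]
default_intron_pct: 1.5
boundary_share: 0.5
spliced_read_fraction: 0.02
retention_sd_logit: 0.15

# reference-donor PSI (%) and normalised expression, per genotype class
psi_by_genotype: [96.4, 94.5, 94.1]
psi_sd_logit: 0.25
expression_by_genotype: [9.244, 9.436, 9.628]
expression_sd: 0.25
cohort_effects: [0.0, 0.05, -0.05]

read_depth: 5000
nb_dispersion: 50.0
read_length: 100
seed: 0
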