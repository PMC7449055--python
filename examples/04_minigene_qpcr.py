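"""Mini-gene qPCR splicing ratios for the two plasmid alleles.

Simulates triplicate qPCR plates for K- and A-allele mini-gene constructs
(standard-curve wells plus experimental wells at four junction assays),
quantifies spliced and unspliced transcripts relative to the reference
genes, and contrasts per-sample splicing ratios between alleles with a
Student's t-test at the 12-test Bonferroni threshold.
"""

from junctionqtl.qpcr import summarize_plate
from junctionqtl.synthetic_data import SimulationConfig, simulate_qpcr_plate

cfg = SimulationConfig(seed=4)
plate = simulate_qpcr_plate(cfg)
print(f"plate: {len(plate)} wells "
      f"({(plate['dilution'].notna()).sum()} standard-curve, "
      f"{(plate['dilution'].isna()).sum()} experimental)")

table = summarize_plate(plate, n_tests=12)
ratio = table[table["measurement"] == "splicing_ratio"]
print("\nSplicing ratio (spliced:unspliced) per junction, mean +/- SD across samples:")
for row in ratio.itertuples():
    flag = "significant" if row.significant else "ns"
    print(
        f"  junction {int(row.junction):2d}:  K {row.mean_K:8.3f} (+/-{row.sd_K:.3f})"
        f"   A {row.mean_A:8.3f} (+/-{row.sd_A:.3f})   p={row.p:.3g}  [{flag}]"
    )
print(f"\nBonferroni threshold (3 measurements x 4 junctions): {ratio['threshold'].iloc[0]:.4f}")
print("junctions 3 and 7 show the allele-dependent splicing-efficiency effect;"
      "\njunctions 5 and 13 are near-equivalent between alleles, as configured.")
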