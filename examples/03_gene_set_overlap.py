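"""Gene-set overlap between a canonical miRNA contrast and its isoforms.

Simulates count matrices for a mimic-control group plus five treatments
(miR, PlusA, TrimA, TrimAG, TrimAGU) with planted regulated gene sets:
the one-base 3' variants share a large core with the canonical contrast,
the deeper trims regulate a mostly different set. Runs the DE stand-in,
builds down-regulated sets at >=1.5-fold with adjusted p < 0.05, and prints
the three-way Venn regions.
"""

import isomirkit as ik

res = ik.simulate_counts(ik.CountSimConfig(seed=7, dispersion=0.0))

down = {}
for treatment in ("miR", "PlusA", "TrimA", "TrimAG", "TrimAGU"):
    table = ik.naive_count_test(
        res.matrices["MC"], res.matrices[treatment], contrast=f"{treatment}_vs_MC"
    )
    up_set, down_set = ik.de_sets(table, fc_threshold=1.5, alpha=0.05)
    planted_up, planted_down = res.planted_sets[treatment]
    print(f"{treatment:8s} up {len(up_set):4d} (planted {len(planted_up):4d})   "
          f"down {len(down_set):4d} (planted {len(planted_down):4d})")
    down[treatment] = down_set

print("\nconcordant trio (miR / PlusA / TrimA), down-regulated:")
for region, size in ik.venn_partition(
    {t: down[t] for t in ("miR", "PlusA", "TrimA")}
).region_sizes().items():
    print(f"  {region:22s} {size}")

print("\ndivergent trio (miR / TrimAG / TrimAGU), down-regulated:")
for region, size in ik.venn_partition(
    {t: down[t] for t in ("miR", "TrimAG", "TrimAGU")}
).region_sizes().items():
    print(f"  {region:22s} {size}")

# At zero noise the recovered regions equal the planted design exactly: the
# trio shares a 120-gene core with 20 private genes each, while the deeper
# trims share nothing with miR and 200 genes with each other.
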