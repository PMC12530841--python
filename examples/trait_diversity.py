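"""Descriptive statistics and Shannon-Weaver diversity for DUS traits.

Builds a small graded trait table (including the classic bulbil
presence/absence pattern: 110 of 113 accessions carry bulbils) and prints the
per-trait summary a germplasm survey would tabulate.
"""

import pandas as pd

import germdiv as gd

# 113 accessions: a binary bulbil trait and a 3-class leaf-color trait
codes = pd.DataFrame({
    "bulbil": [1.0] * 110 + [0.0] * 3,
    "leaf_color": ([1.0] * 40 + [2.0] * 50 + [3.0] * 23),
}, index=[f"CY{i + 1:03d}" for i in range(113)])
descriptors = {
    "bulbil": gd.TraitDescriptor("bulbil", "Bulbil presence", "qualitative", (0, 1)),
    "leaf_color": gd.TraitDescriptor("leaf_color", "Leaf color", "qualitative", (1, 2, 3)),
}
table = gd.TraitTable(codes=codes, descriptors=descriptors)

for trait in table.trait_ids:
    s = gd.descriptive_stats(table, trait)
    print(f"{trait:>10}: mean={s.mean:.2f} SD={s.sd:.2f} "
          f"CV%={s.cv_percent:.2f} H'={s.shannon_h:.2f}")

print()
print("The population-SD convention gives the bulbil trait mean 0.97, SD 0.16,")
print("CV 16.51% and H' 0.12; a higher H' means trait classes are more evenly")
print("spread across the panel (max ln k for k equally frequent classes).")
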