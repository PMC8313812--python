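"""Alpha and beta diversity of a paired community: rarefaction curves,
Kruskal-Wallis/Dunn comparison, Bray-Curtis PCoA and a UPGMA tree."""

import numpy as np

import coresponse as cr
from coresponse import diversity as dv

table, taxonomy, design, _ = cr.generate_paired_design(
    n_bacteria=80, n_fungi=20, zero_rate=0.3, seed=7)

totals = table.values().sum(axis=0)
print(f"sample totals: {totals.min():.0f}-{totals.max():.0f} reads")

# Subsample without replacement on a depth grid (10 iterations per depth),
# standardizing every sample to the same final depth.
increment = int(totals.min() // 10)
series = dv.rarefaction_series(table, increment=increment, iterations=10,
                               max_depth=10 * increment, seed=1)
final = series.final_depth_values("shannon")
print(f"standardized depth {series.max_depth}: "
      f"mean Shannon (bits) per sample group:")
cmp_res = dv.compare_alpha(series, design, metric="shannon")
for group, values in cmp_res.group_values.items():
    print(f"  {group}: {values.mean():.3f} (n={len(values)}; "
          f"letter {cmp_res.letters[group]!r})")
print(f"Kruskal-Wallis H={cmp_res.kruskal_h:.2f}, p={cmp_res.kruskal_p:.3g} "
      "(groups sharing a letter are indistinguishable at alpha=0.05)")

# Beta diversity at the phylum level.
agg = dv.aggregate_to_rank(cr.to_relative(table), taxonomy, "phylum")
dm = dv.bray_curtis(agg)
ordn = dv.pcoa(dm)
explained = ordn.proportion_explained[:2]
print(f"PCoA axes 1-2 explain {100 * explained.sum():.0f}% of the "
      "Bray-Curtis variation among samples")
print("UPGMA tree:", dv.upgma(dm))
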