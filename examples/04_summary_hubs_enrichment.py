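"""Summarize an inferred network the way the study's network-parameter
table does: kingdom-partitioned counts, +/- ratios, hubs and enrichment."""

import coresponse as cr

table, taxonomy, design, truth = cr.generate_paired_design(
    n_bacteria=60, n_fungi=15,
    module_spec=[cr.ModuleSpec(6, 1, 0.95), cr.ModuleSpec(5, -1, 0.95)],
    zero_rate=0.3, seed=8,
)
filtered = cr.filter_prevalence(cr.to_relative(table), design,
                                "compartment", 4)["BS"]
ratios = cr.compute_ratios(filtered, design, "BS")
net = cr.build_network(ratios, taxonomy,
                       cr.NetworkConfig(seed=8, n_perm=300, n_boot=0))

summary = cr.summarize(net, taxonomy)
print(summary.as_series().to_string())
print()
print("A ratio above 1 means cooperation (positive co-response) dominates "
      "antagonism within that partition.")

hubs = cr.find_hubs(net, fraction=0.01)
degrees = dict(net.graph.degree())
print(f"\nhubs (top 1% degrees, cutoff {hubs.cutoff_degree}"
      f"{', tie-expanded' if hubs.tie_expanded else ''}):")
for h in hubs.hubs:
    print(f"  {h}: degree {degrees[h]}, {taxonomy[h].phylum}")

# Which phyla are over-represented among network nodes relative to the
# prevalence-filtered community the network was built from?
enriched = cr.enrich_taxa(net, filtered, taxonomy, rank="phylum", alpha=0.01)
print("\nphylum enrichment (hypergeometric upper tail):")
for r in sorted(enriched, key=lambda r: r.p)[:5]:
    flag = "  <- enriched (p < 0.01)" if r.enriched else ""
    print(f"  {r.taxon}: {r.network_count}/{r.community_count} in network, "
          f"p={r.p:.3g}{flag}")
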