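"""Generate a paired full-/deficit-irrigation community with planted
co-response modules and inspect what the ground truth contains."""

import numpy as np

import coresponse as cr

table, taxonomy, design, truth = cr.generate_paired_design(
    n_bacteria=60, n_fungi=15, n_reps=3,
    module_spec=[cr.ModuleSpec(size=5, sign=1, strength=0.95),
                 cr.ModuleSpec(size=4, sign=-1, strength=0.95)],
    zero_rate=0.3, seed=42,
)

print(f"table: {table.shape[0]} OTUs x {table.shape[1]} samples "
      f"({', '.join(table.sample_ids)})")
print(f"zero fraction: {(table.values() == 0).mean():.2f} "
      "(dropout hits background OTUs only)")
print(f"planted modules: {sorted(set(m for m in truth.modules.values() if m is not None))}")
print(f"planted edges: {len(truth.planted_edges)} "
      f"({sum(1 for *_, s in truth.planted_edges if s > 0)} positive, "
      f"{sum(1 for *_, s in truth.planted_edges if s < 0)} negative)")

# The community prevalence rule: an OTU represents a soil/treatment cell
# when it is seen in at least 2 of that cell's 3 replicates.
community = cr.filter_prevalence(table, design, "compartment_treatment", 2)["BS"]
# The network rule is stricter: at least 4 of the compartment's 6 samples.
network_input = cr.filter_prevalence(table, design, "compartment", 4)["BS"]
print(f"community filter keeps {community.shape[0]} OTUs; "
      f"network filter keeps {network_input.shape[0]}")
print("module members always survive:",
      all(o in network_input.otu_ids
          for o, m in truth.modules.items() if m is not None))
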