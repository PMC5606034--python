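"""Community structure of the two diet groups: filtering, composition,
diversity, ordination, and the ANOSIM separation test.

Counts are filtered (count > 3 in at least one sample), normalised to
relative abundance, and summarised at genus level; Bray-Curtis distances
feed NMDS and ANOSIM.
"""

import rumenomics as rm

study = rm.simulate_study(rm.SyntheticConfig(seed=1))
table = study.otu_table

filtered = rm.filter_min_count(table, min_count=3)
abund = rm.relative_abundance(filtered)
print(f"count filter: {len(table.otu_ids)} -> {len(filtered.otu_ids)} OTUs")
print(f"detectable (>= 1% somewhere): {len(rm.detectable_otus(abund, 0.01))} OTUs")

genus = rm.aggregate_taxa(abund, "genus")
overlap = rm.group_overlap(genus)
print(f"genera shared between diets: {len(overlap['shared'])}, "
      f"LC-only {len(overlap['only_LC'])}, MC-only {len(overlap['only_MC'])}")
change = rm.percent_change(genus, "Clostridium_IV")
print(f"Clostridium_IV abundance change (MC vs LC): {change:+.0f}%")

alpha = rm.alpha_diversity(abund)
tests = rm.diversity_group_test(alpha, abund.groups)
print(f"\nShannon (nats) per sample:\n{alpha['shannon'].round(3).to_string()}")
print(f"group difference p-values: shannon {tests.loc['shannon', 'p']:.3f}, "
      f"simpson {tests.loc['simpson', 'p']:.3f}")

dist = rm.bray_curtis(abund)
ordination = rm.nmds(dist, k=2, seed=1)
separation = rm.anosim(dist, abund.groups, n_perm=999, seed=1)
print(f"\nNMDS stress: {ordination.stress:.4f} "
      "(below ~0.1 means the 2-D map represents the distances well)")
print(f"ANOSIM R = {separation.r:.2f}, p = {separation.p_value:.3f} "
      "(R near 1: groups well separated; p is permutation-based and cannot "
      "go below 0.1 with only 3 animals per group and 999 label shuffles)")
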