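"""Post-assembly filtering: depth masking, theta outliers, MAC, thinning.

Simulates a small dataset and pushes it through the standard filter chain,
printing the per-rule counts a real run would log.
"""

import demearc as da

config = da.SimulationConfig(
    n_loci=2000, samples_per_deme=(10,), mu=2.8e-7,
    missing_rate=0.2, rng_seed=2)
data = da.generate("CONST", {"N_DEME": 1e4, "N_ANC": 1e4, "T_0": 5e3}, config)
table = data.site_table
print(f"input: {table.n_sites} sites, {int(table.is_variant.sum())} variants")

# genotypes below 5x or above the per-sample 97.5% DP quantile become missing
table, report = da.mask_by_depth(table, min_dp=5, high_percentile=0.975)
print(f"depth mask: {report['rule_low_dp_masked']} low-DP and "
      f"{report['rule_high_dp_masked']} high-DP genotypes masked")
table = da.recompute_alleles(table)  # fully-masked alleles -> invariant

# per-locus Watterson theta flags overmerged (suspiciously variable) loci
records = da.locus_theta(table)
blacklist = da.flag_overmerged(records, percentile=0.995)
table, bl_report = da.apply_blacklist(table, blacklist)
print(f"theta filter: {len(blacklist)} loci blacklisted "
      f"({bl_report['n_sites_removed']} sites removed)")

table = da.filter_site_presence(table, 0.5, table.samples)
print(f"50% presence: {table.n_sites} sites kept")
table = da.filter_mac(table, min_mac=3)
print(f"MAC >= 3: {int(table.is_variant.sum())} variants kept")
thinned = da.thin_first_variant(table)
print(f"thinned to first variant per locus: {thinned.n_sites} unlinked variants")
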