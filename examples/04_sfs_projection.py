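"""Folded SFS construction with hypergeometric projection.

Missing genotypes mean different sites are genotyped in different numbers
of lineages; projection maps every site onto a common (smaller) sample
size by averaging over subsamples, so no site is wasted.
"""

import numpy as np

import demearc as da

config = da.SimulationConfig(
    n_loci=4000, samples_per_deme=(8,), mu=2.8e-7,
    missing_rate=0.3, rng_seed=4)
data = da.generate("CONST", {"N_DEME": 1e4, "N_ANC": 1e4, "T_0": 5e3}, config)
table, _ = da.mask_by_depth(data.site_table)
table = da.recompute_alleles(table)
thinned = da.thin_first_variant(table)
print(f"unlinked variants: {thinned.n_sites}")

# single-site projection: 1 minor allele of 4 lineages projected into 2
print("project_site(d=1, n=4, m=2) =", da.project_site(1, 4, 2))

from demearc.sfstools import choose_projection

sfs = choose_projection(thinned, thinned.samples, (5, 6, 7), 0.7)
p = sfs.provenance
print(f"chosen projection: {p['projection_individuals']} individuals "
      f"({sfs.n_lineages} lineages), {p['n_sites_used']} sites used, "
      f"{p['n_sites_dropped_low_coverage']} dropped for low coverage")
print("folded SFS (class 0 = monomorphic-after-projection, masked):")
print(np.round(sfs.counts, 1))
print("Under constant size the polymorphic classes should decay like the")
print("folded 1/i neutral expectation.")
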