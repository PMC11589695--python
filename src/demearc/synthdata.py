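"""Coalescent simulation of RAD-style genotype datasets with known truth.

Datasets emulate ddRAD genotype tables: many short (default 121 bp)
independent loci, biallelic SNPs on an invariant background, diploid
individuals sampled from one or two demes, missing genotypes from both
per-(sample, locus) allelic dropout and genotype-level dropout, and
overdispersed per-genotype sequencing depth. Trees are simulated with
msprime under one of the demographic models in :mod:`demearc.models`;
mutations are placed under a finite-sites Jukes-Cantor model and sites that
end up with more than two alleles are dropped (with a logged count), so every
variant site is biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .models import get_model, to_msprime_demography, validate_params
from .sitetable import MISSING, SampleMetadata, SiteTable

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "apply_missingness",
    "assign_depths",
    "generate",
    "default_popmap",
]

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the ddRAD system the package emulates: 121-bp loci
    (150-bp reads trimmed by 5 + 24 bp), mutation rate 2.8e-9 per site per
    generation, ~35% missing genotypes and per-sample mean depths between
    18x and 77x.
    """

    n_loci: int
    samples_per_deme: tuple[int, ...]
    locus_length_bp: int = 121
    mu: float = 2.8e-9
    missing_rate: float = 0.35
    locus_dropout_rate: float = 0.0
    depth_mean_range: tuple[float, float] = (18.0, 77.0)
    depth_dispersion: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be a positive integer")
        if self.locus_length_bp < 1:
            raise ValueError("locus_length_bp must be >= 1")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not all(s >= 1 for s in self.samples_per_deme):
            raise ValueError("every deme needs at least one diploid sample")
        for name in ("missing_rate", "locus_dropout_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        lo, hi = self.depth_mean_range
        if not (0 < lo <= hi):
            raise ValueError("depth_mean_range must be positive with min <= max")


@dataclass
class SimulatedDataset:
    """A SiteTable plus the demographic truth that generated it."""

    site_table: SiteTable
    truth: dict

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"model = {self.truth['model_id']}\n")
            fh.write(f"rng_seed = {self.truth['rng_seed']}\n")
            for key, value in sorted(self.truth["params"].items()):
                fh.write(f"param.{key} = {value:g}\n")
            for key, value in self.truth.get("config", {}).items():
                fh.write(f"config.{key} = {value}\n")


def _sample_names(samples_per_deme) -> tuple[list[str], list[str]]:
    names, demes = [], []
    for d, n in enumerate(samples_per_deme, start=1):
        for i in range(1, n + 1):
            names.append(f"deme{d}_ind{i:02d}")
            demes.append(f"deme{d}")
    return names, demes


def default_popmap(config: SimulationConfig) -> SampleMetadata:
    """Popmap for a simulated dataset (one island, habitat 'synthetic')."""
    import pandas as pd

    names, demes = _sample_names(config.samples_per_deme)
    return SampleMetadata(pd.DataFrame({
        "sample": names, "deme": demes,
        "island": "island1", "habitat": "synthetic",
    }))


def simulate_dataset(model, params: dict, config: SimulationConfig) -> SimulatedDataset:
    """Simulate independent RAD loci under a demographic model.

    Each locus is an independent non-recombining coalescent genealogy of
    ``locus_length_bp`` discrete sites; mutations land under Jukes-Cantor.
    Sites with more than two alleles are dropped and counted. Returns the
    full variant + invariant site table with no missing data (apply
    :func:`apply_missingness` / :func:`assign_depths` afterwards).
    """
    spec = get_model(model)
    p = validate_params(spec, params)
    if len(config.samples_per_deme) != spec.n_demes:
        raise ValueError(
            f"model {spec.model_id} has {spec.n_demes} deme(s) but "
            f"samples_per_deme has {len(config.samples_per_deme)} entries")
    demography = to_msprime_demography(spec, p)
    sample_sets = {
        f"deme{d}": n for d, n in enumerate(config.samples_per_deme, start=1)
    }
    n_ind = sum(config.samples_per_deme)
    L = config.locus_length_bp
    n_sites = config.n_loci * L

    rng = np.random.default_rng(config.rng_seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)

    genotypes = np.zeros((n_sites, n_ind), dtype=np.int8)
    ref = rng.choice(_BASES, size=n_sites)
    alt = np.full(n_sites, ".", dtype=object)

    n_multi = 0
    replicates = msprime.sim_ancestry(
        samples=sample_sets, demography=demography, ploidy=2,
        sequence_length=L, discrete_genome=True,
        num_replicates=config.n_loci, random_seed=int(anc_seed),
    )
    # hoisted out of the per-locus loop: RateMap / model construction and
    # provenance encoding dominate sim_mutations runtime at this locus count
    mutation_rate = msprime.RateMap.uniform(L, config.mu)
    mutation_model = msprime.JC69()
    for locus, ts in enumerate(replicates):
        mts = msprime.sim_mutations(
            ts, rate=mutation_rate, model=mutation_model,
            random_seed=int(mut_seed + locus), discrete_genome=True,
            record_provenance=False,
        )
        if mts.num_sites == 0:
            continue
        base = locus * L
        gm = mts.genotype_matrix()  # (sites, 2 * n_ind) allele indices
        site_positions = mts.tables.sites.position.astype(np.int64)
        alleles_per_site = [v.alleles for v in mts.variants()]
        for row, pos0, var_alleles in zip(gm, site_positions,
                                          alleles_per_site):
            observed = np.unique(row)
            if len(observed) > 2:
                n_multi += 1
                continue
            pos = base + int(pos0)
            alleles = [a for a in var_alleles if a is not None]
            if len(observed) == 1:
                ref[pos] = var_alleles[int(observed[0])]
                continue
            # map the two observed alleles to ref (ancestral if present) / alt
            a0, a1 = int(observed[0]), int(observed[1])
            anc = alleles[0]
            anc_idx = var_alleles.index(anc) if anc in alleles else a0
            if a1 == anc_idx:
                ref_idx, alt_idx = a1, a0
            else:
                ref_idx, alt_idx = (a0, a1)
            dosage = (row == alt_idx).astype(np.int8)
            genotypes[pos] = dosage.reshape(n_ind, 2).sum(axis=1)
            ref[pos] = var_alleles[ref_idx]
            alt[pos] = var_alleles[alt_idx]

    names, _ = _sample_names(config.samples_per_deme)
    table = SiteTable(
        samples=names,
        locus_names=np.array(
            [f"locus_{k}" for k in range(1, config.n_loci + 1)], dtype=object),
        locus_lengths=np.full(config.n_loci, L, dtype=np.int64),
        locus_index=np.repeat(
            np.arange(config.n_loci, dtype=np.int32), L),
        positions=np.tile(np.arange(1, L + 1, dtype=np.int32), config.n_loci),
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        depth=None,
        n_multiallelic_dropped=n_multi,
    )
    truth = {
        "model_id": spec.model_id,
        "params": p,
        "rng_seed": int(config.rng_seed),
        "config": {
            "n_loci": config.n_loci,
            "locus_length_bp": L,
            "mu": config.mu,
            "samples_per_deme": ",".join(map(str, config.samples_per_deme)),
        },
    }
    return SimulatedDataset(site_table=table, truth=truth)


def apply_missingness(
    data: SimulatedDataset,
    missing_rate: float,
    locus_dropout_rate: float = 0.0,
    rng_seed: int = 0,
) -> SimulatedDataset:
    """Set genotypes missing by locus dropout then genotype-level dropout.

    A (sample, locus) pair drops out entirely with probability
    ``locus_dropout_rate`` (mimicking allelic dropout at a restriction site);
    each remaining genotype is independently set missing with probability
    ``missing_rate``. Overall expected missingness is
    ``d + (1 - d) * m``. The degenerate ``locus_dropout_rate = 1`` is
    allowed and blanks the whole table.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not (0.0 <= locus_dropout_rate <= 1.0):
        raise ValueError("locus_dropout_rate must lie in [0, 1]")
    table = data.site_table
    if missing_rate == 0.0 and locus_dropout_rate == 0.0:
        return data
    rng = np.random.default_rng(rng_seed)
    g = table.genotypes.copy()
    if locus_dropout_rate > 0.0:
        drop = rng.random((table.n_loci, table.n_samples)) < locus_dropout_rate
        g[drop[table.locus_index]] = MISSING
    if missing_rate > 0.0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    depth = None
    if table.depth is not None:
        depth = np.where(g == MISSING, 0, table.depth).astype(np.int32)
    new_table = replace(table, genotypes=g, depth=depth)
    return SimulatedDataset(site_table=new_table, truth=dict(data.truth))


def assign_depths(
    data: SimulatedDataset,
    depth_mean_range: tuple[float, float],
    rng_seed: int = 0,
    dispersion: float = 0.3,
) -> SimulatedDataset:
    """Draw per-genotype DP from a negative binomial around per-sample means.

    Each sample's mean depth is uniform over ``depth_mean_range``; genotype
    DP has variance ``mean + dispersion * mean**2`` (overdispersed RAD
    coverage). Missing genotypes receive DP = 0.
    """
    lo, hi = depth_mean_range
    if not (0 < lo <= hi):
        raise ValueError("depth_mean_range must be positive with min <= max")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    table = data.site_table
    rng = np.random.default_rng(rng_seed)
    means = rng.uniform(lo, hi, size=table.n_samples)
    r = 1.0 / dispersion
    p = r / (r + means)  # success prob per sample
    depth = rng.negative_binomial(
        r, p[np.newaxis, :], size=table.genotypes.shape)
    depth = np.where(table.genotypes == MISSING, 0, depth).astype(np.int32)
    new_table = replace(table, depth=depth)
    truth = dict(data.truth)
    return SimulatedDataset(site_table=new_table, truth=truth)


def generate(model, params: dict, config: SimulationConfig) -> SimulatedDataset:
    """Full generator: simulate, apply missingness, assign depths.

    Seeds for the three stages are derived deterministically from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    miss_seed, depth_seed = rng.integers(1, 2**31 - 1, size=2)
    data = simulate_dataset(model, params, config)
    data = apply_missingness(
        data, config.missing_rate, config.locus_dropout_rate, int(miss_seed))
    data = assign_depths(
        data, config.depth_mean_range, int(depth_seed), config.depth_dispersion)
    return data
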