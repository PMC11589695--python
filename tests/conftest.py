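"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit pair enumeration,
exhaustive subsampling, literal formula transcription) so they stay
independent of the vectorized implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from demearc.sitetable import MISSING, SiteTable

# ---------------------------------------------------------------------------
# table construction helpers


def make_table(genotypes, depth=None, locus_index=None, n_loci=None,
               locus_length=121, positions=None, alt=None, samples=None):
    """Build a SiteTable from a dosage matrix (rows = sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{i+1:02d}" for i in range(n_samples)]
    if locus_index is None:
        locus_index = np.zeros(n_sites, dtype=np.int32)
    else:
        locus_index = np.asarray(locus_index, dtype=np.int32)
    if n_loci is None:
        n_loci = int(locus_index.max()) + 1 if n_sites else 1
    if positions is None:
        positions = np.zeros(n_sites, dtype=np.int32)
        for li in range(n_loci):
            where = np.flatnonzero(locus_index == li)
            positions[where] = np.arange(1, len(where) + 1)
    if alt is None:
        has_alt = (g > 0).any(axis=1)
        alt = np.where(has_alt, "T", ".").astype(object)
    else:
        alt = np.asarray(alt, dtype=object)
    return SiteTable(
        samples=list(samples),
        locus_names=np.array([f"locus_{k+1}" for k in range(n_loci)],
                             dtype=object),
        locus_lengths=np.full(n_loci, locus_length, dtype=np.int64),
        locus_index=locus_index,
        positions=np.asarray(positions, dtype=np.int32),
        ref=np.full(n_sites, "A", dtype=object),
        alt=alt,
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


def random_genotypes(rng, n_sites, n_samples, missing=0.3):
    """Random biallelic dosage matrix with missing entries."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    g = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    g[rng.random(g.shape) < missing] = MISSING
    return g


# ---------------------------------------------------------------------------
# oracles


def lineage_alleles(row):
    """Diploid dosages -> list of haploid allele states (0/1)."""
    out = []
    for dose in row:
        if dose == MISSING:
            continue
        out.extend([1] * int(dose) + [0] * (2 - int(dose)))
    return out


def pi_oracle(genotypes):
    """Exhaustive within-group pair enumeration: (numerator, denominator)."""
    num = den = 0
    for row in np.asarray(genotypes):
        alleles = lineage_alleles(row)
        for a, b in itertools.combinations(alleles, 2):
            den += 1
            num += int(a != b)
    return num, den


def dxy_oracle(genotypes_a, genotypes_b):
    """Exhaustive cross-group pair enumeration: (numerator, denominator)."""
    num = den = 0
    for row_a, row_b in zip(np.asarray(genotypes_a), np.asarray(genotypes_b)):
        for a in lineage_alleles(row_a):
            for b in lineage_alleles(row_b):
                den += 1
                num += int(a != b)
    return num, den


def wc_components_oracle(n1, n2, p1, p2, h1, h2):
    """Literal scalar transcription of the Weir-Cockerham (1984) two-pop
    variance components a, b, c for one biallelic site."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - 1.0 / (n_bar - 1)
        * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def folded_projection_oracle(minor_counts, n, m):
    """Brute-force folded SFS: average over all C(n, m) lineage subsamples."""
    from demearc.sfstools import fold_1d

    unfolded = np.zeros(m + 1)
    for d in minor_counts:
        alleles = [1] * int(d) + [0] * (n - int(d))
        combos = list(itertools.combinations(range(n), m))
        for combo in combos:
            j = sum(alleles[i] for i in combo)
            unfolded[j] += 1.0 / len(combos)
    return fold_1d(unfolded)


def welch_oracle(a, b):
    """Direct evaluation of Welch's t and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def folded_neutral_expectation(n):
    """Folded constant-size SFS expectation (proportional), classes 1..n/2."""
    xi = np.zeros(n // 2 + 1)
    for j in range(1, n // 2 + 1):
        xi[j] = 1.0 / j + (1.0 / (n - j) if j != n - j else 0.0)
    return xi[1:] / xi[1:].sum()


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated constant-size dataset reused across tests."""
    from demearc.synthdata import SimulationConfig, generate

    config = SimulationConfig(
        n_loci=400, samples_per_deme=(8,), mu=2.8e-7, missing_rate=0.2,
        locus_dropout_rate=0.05, rng_seed=42)
    return generate(
        "CONST", {"N_DEME": 1e4, "N_ANC": 1e4, "T_0": 5000.0}, config)
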