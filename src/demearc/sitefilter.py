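"""Post-assembly masking and filtering of RAD genotype tables.

The chain mirrors common ddRAD practice: depth-based genotype masking
(drop calls below a minimum DP and calls above a per-sample high-DP
quantile, the latter flagging overmerged paralogous clusters), presence
(missingness) filters, a minor-allele-count filter, thinning to one variant
per locus, and a bespoke per-locus Watterson-theta outlier filter that
blacklists suspiciously variable (overmerged) loci.

All filters are deterministic and order-stable: they only remove sites or
set genotypes missing, never alter retained genotype values. Because depth
masking can exhaust an allele, :func:`recompute_alleles` re-derives each
site's variant/invariant status afterwards (on by default in the pipeline).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .sitetable import MISSING, SiteTable

__all__ = [
    "mask_by_depth",
    "recompute_alleles",
    "filter_site_presence",
    "filter_mac",
    "thin_first_variant",
    "locus_theta",
    "flag_overmerged",
    "apply_blacklist",
    "LocusThetaRecord",
    "read_blacklist",
    "write_blacklist",
]

logger = logging.getLogger("demearc")


class DepthMaskError(ValueError):
    pass


def mask_by_depth(
    table: SiteTable, min_dp: int = 5, high_percentile: float = 0.975
) -> tuple[SiteTable, dict]:
    """Mask genotypes with DP below ``min_dp`` or above a per-sample quantile.

    The high-DP rule is evaluated per genotype against the
    ``high_percentile`` quantile (linear interpolation) of that sample's DP
    distribution over its genotyped sites. Returns the masked table and a
    report with per-rule counts.
    """
    if table.depth is None:
        raise DepthMaskError(
            "table carries no DP field; depth masking cannot be applied -- "
            "disable it explicitly if the input has no depth information")
    if not (0.0 < high_percentile <= 1.0):
        raise ValueError("high_percentile must lie in (0, 1]")
    if min_dp < 0:
        raise ValueError("min_dp must be >= 0")
    called = table.genotypes >= 0
    dp = table.depth
    thresholds = np.full(table.n_samples, np.inf)
    for j in range(table.n_samples):
        vals = dp[called[:, j], j]
        if vals.size:
            thresholds[j] = np.quantile(vals, high_percentile)
    low = called & (dp < min_dp)
    high = called & (dp > thresholds[np.newaxis, :])
    g = table.genotypes.copy()
    g[low | high] = MISSING
    report = {
        "rule_low_dp_masked": int(low.sum()),
        "rule_high_dp_masked": int(high.sum()),
        "min_dp": min_dp,
        "high_percentile": high_percentile,
        "thresholds_per_sample": thresholds.tolist(),
    }
    return replace(table, genotypes=g), report


def recompute_alleles(table: SiteTable) -> SiteTable:
    """Re-derive variant/invariant status after masking.

    A variant site whose ALT allele was fully masked becomes invariant; a
    site fixed for ALT is relabelled so the remaining allele is the REF of
    an invariant record (dosages rewritten accordingly).
    """
    ref_n, alt_n = table.allele_counts()
    alt = table.alt.copy()
    ref = table.ref.copy()
    g = table.genotypes.copy()
    was_variant = table.is_variant
    to_invariant = was_variant & (alt_n == 0)
    alt[to_invariant] = "."
    fixed_alt = was_variant & (alt_n > 0) & (ref_n == 0)
    for i in np.flatnonzero(fixed_alt):
        ref[i] = alt[i]
        alt[i] = "."
        row = g[i]
        row[row > 0] = 0
    return replace(table, ref=ref, alt=alt, genotypes=g)


def filter_site_presence(
    table: SiteTable, min_presence: float, scope
) -> SiteTable:
    """Drop sites genotyped in fewer than ceil(min_presence * |scope|) samples.

    ``scope`` is a collection of sample names (or indices) over which
    presence is counted; the "at least" boundary is inclusive.
    """
    if not (0.0 < min_presence <= 1.0):
        raise ValueError("min_presence must lie in (0, 1]")
    scope = list(scope)
    if not scope:
        raise ValueError("presence filter needs a nonempty sample scope")
    if isinstance(scope[0], str):
        idx = table.sample_indices(scope)
    else:
        idx = np.asarray(scope, dtype=np.intp)
    threshold = math.ceil(min_presence * len(idx))
    n_called = (table.genotypes[:, idx] >= 0).sum(axis=1)
    keep = n_called >= threshold
    if not keep.any():
        logger.warning(
            "presence filter at %.2f removed every site", min_presence)
    return table.take_sites(keep)


def filter_mac(table: SiteTable, min_mac: int = 3) -> SiteTable:
    """Remove variant sites with minor allele count below ``min_mac``.

    Invariant sites are untouched; ``min_mac = 0`` is the identity.
    """
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    if min_mac == 0:
        return table.take_sites(np.ones(table.n_sites, dtype=bool))
    ref_n, alt_n = table.allele_counts()
    mac = np.minimum(ref_n, alt_n)
    drop = table.is_variant & (mac < min_mac)
    return table.take_sites(~drop)


def thin_first_variant(table: SiteTable) -> SiteTable:
    """Keep only the first (smallest-position) variant per locus.

    Invariant sites are dropped; the result has at most one variant per
    locus and the operation is idempotent.
    """
    variant_idx = np.flatnonzero(table.is_variant)
    if variant_idx.size == 0:
        return table.take_sites(variant_idx)
    order = np.lexsort((table.positions[variant_idx],
                        table.locus_index[variant_idx]))
    ordered = variant_idx[order]
    first = np.ones(ordered.size, dtype=bool)
    first[1:] = np.diff(table.locus_index[ordered]) != 0
    return table.take_sites(np.sort(ordered[first]))


@dataclass(frozen=True)
class LocusThetaRecord:
    """Per-locus segregating-site count and Watterson theta."""

    locus_id: str
    S: int
    n_bar: float
    theta_w: float
    computable: bool


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def locus_theta(table: SiteTable) -> list[LocusThetaRecord]:
    """Watterson's theta per locus: theta_w = S / a_n.

    ``S`` counts polymorphic sites in the locus; ``n`` is the rounded mean
    number of genotyped haploid lineages across the locus's sites (loci
    with n < 2 are flagged uncomputable).
    """
    n_lineages = 2 * (table.genotypes >= 0).sum(axis=1)
    is_var = table.is_variant
    records = []
    n_loci = table.n_loci
    S_per = np.bincount(table.locus_index[is_var], minlength=n_loci)
    sites_per = np.bincount(table.locus_index, minlength=n_loci)
    lin_sum = np.bincount(
        table.locus_index, weights=n_lineages.astype(float), minlength=n_loci)
    for li in range(n_loci):
        if sites_per[li] == 0:
            continue
        n_bar = lin_sum[li] / sites_per[li]
        n = int(round(n_bar))
        S = int(S_per[li])
        if n < 2:
            records.append(LocusThetaRecord(
                str(table.locus_names[li]), S, n_bar, math.nan, False))
            continue
        theta = S / _harmonic(n) if S > 0 else 0.0
        records.append(LocusThetaRecord(
            str(table.locus_names[li]), S, n_bar, theta, True))
    return records


def flag_overmerged(
    records: list[LocusThetaRecord], percentile: float = 0.995
) -> set[str]:
    """Blacklist loci whose theta_w exceeds the empirical percentile.

    Uses the linear-interpolation quantile over all computable theta values;
    loci strictly above the threshold are flagged.
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    values = np.array([r.theta_w for r in records if r.computable])
    if values.size == 0:
        return set()
    if values.size < 200:
        logger.warning(
            "theta outlier filter on only %d loci: quantile unstable",
            values.size)
    threshold = np.quantile(values, percentile)
    return {
        r.locus_id for r in records
        if r.computable and r.theta_w > threshold
    }


def apply_blacklist(
    table: SiteTable, blacklist
) -> tuple[SiteTable, dict]:
    """Remove every site of the blacklisted loci.

    Unknown locus IDs are ignored with a warning. Returns the reduced table
    and a report of removed locus/site counts.
    """
    blacklist = set(blacklist)
    known = set(map(str, table.locus_names))
    unknown = blacklist - known
    if unknown:
        logger.warning(
            "blacklist contains %d unknown locus id(s); ignored", len(unknown))
    bad_locus = np.isin(
        np.asarray(table.locus_names, dtype=object),
        np.array(sorted(blacklist & known), dtype=object),
    )
    drop = bad_locus[table.locus_index]
    report = {
        "n_loci_blacklisted": int(len(blacklist & known)),
        "n_loci_with_sites_removed": int(
            len(np.unique(table.locus_index[drop]))),
        "n_sites_removed": int(drop.sum()),
        "n_unknown_ids": int(len(unknown)),
    }
    return table.take_sites(~drop), report


def read_blacklist(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_blacklist(blacklist, path) -> None:
    with open(path, "w") as fh:
        for locus_id in sorted(blacklist):
            fh.write(f"{locus_id}\n")
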