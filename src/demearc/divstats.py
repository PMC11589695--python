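"""Missing-data-aware diversity and divergence statistics.

pi and D_XY are computed from variant *and* invariant sites as a single
ratio of sums -- total count of pairwise allele differences over total count
of pairwise allele comparisons -- never as a mean of per-site ratios, so
heterogeneous missingness cannot bias the estimate. F_ST is a ratio of
summed variance components (Weir-Cockerham by default, Hudson selectable).
Diploid genotypes contribute two haploid lineages each; half-calls are
treated as missing upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sitefilter import filter_site_presence
from .sitetable import SiteTable

__all__ = [
    "DiversityEstimate",
    "FstEstimate",
    "DemeSummary",
    "pi_within",
    "dxy_between",
    "fst_between",
    "count_site_classes",
    "welch_t",
]


@dataclass(frozen=True)
class DiversityEstimate:
    """Ratio-of-sums estimate: differences / comparisons."""

    statistic: str  # "pi" or "dxy"
    numerator: float
    denominator: float
    n_sites_used: int

    @property
    def value(self) -> float:
        """The estimate; NaN when no comparisons were possible."""
        if self.denominator <= 0:
            return math.nan
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class FstEstimate:
    """F_ST from summed variance components."""

    estimator: str
    component_a: float
    component_b: float
    component_c: float | None
    n_sites_used: int

    @property
    def value(self) -> float:
        if self.estimator == "weir-cockerham":
            total = self.component_a + self.component_b + (self.component_c or 0.0)
            return self.component_a / total if total != 0 else math.nan
        return (self.component_a / self.component_b
                if self.component_b != 0 else math.nan)

    @property
    def defined(self) -> bool:
        if self.estimator == "weir-cockerham":
            return (self.component_a + self.component_b
                    + (self.component_c or 0.0)) != 0
        return self.component_b != 0


@dataclass(frozen=True)
class DemeSummary:
    deme_id: str
    n_individuals: int
    total_sites: int
    polymorphic_sites: int
    private_sites: int
    pi: DiversityEstimate
    excluded: bool  # demes with < 5 individuals are excluded from comparisons


def _deme_counts(table: SiteTable, idx):
    g = table.genotypes[:, idx]
    called = g >= 0
    n_called_ind = called.sum(axis=1)
    n_lineages = 2 * n_called_ind
    alt = np.where(called, g, 0).sum(axis=1)
    return n_called_ind, n_lineages, alt


def pi_within(
    table: SiteTable, deme, min_presence: float = 0.5
) -> DiversityEstimate:
    """Nucleotide diversity within a deme over variant + invariant sites.

    Sites must be genotyped in at least ``min_presence`` of the deme's
    individuals (the deme is filtered independently). Invariant sites add
    to the comparison denominator only.
    """
    deme = list(deme)
    if len(deme) < 2:
        raise ValueError("pi requires a deme of at least two individuals")
    sub = filter_site_presence(table, min_presence, deme)
    idx = sub.sample_indices(deme) if isinstance(deme[0], str) else deme
    _, n_lin, alt = _deme_counts(sub, idx)
    ref = n_lin - alt
    num = (ref.astype(float) * alt).sum()
    den = (n_lin.astype(float) * (n_lin - 1) / 2.0).sum()
    return DiversityEstimate("pi", float(num), float(den), sub.n_sites)


def dxy_between(
    table: SiteTable, demeA, demeB, min_presence: float = 0.5
) -> DiversityEstimate:
    """Absolute divergence D_XY between two demes (ratio of sums).

    Sites must pass the presence threshold within *each* deme. Per site the
    numerator adds the differing cross-deme lineage pairs and the
    denominator all ``n_A * n_B`` cross-deme comparisons.
    """
    demeA, demeB = list(demeA), list(demeB)
    if not demeA or not demeB:
        raise ValueError("both demes must be nonempty")
    sub = filter_site_presence(table, min_presence, demeA)
    sub = filter_site_presence(sub, min_presence, demeB)
    ia = sub.sample_indices(demeA)
    ib = sub.sample_indices(demeB)
    _, nA, altA = _deme_counts(sub, ia)
    _, nB, altB = _deme_counts(sub, ib)
    refA, refB = nA - altA, nB - altB
    num = (refA.astype(float) * altB + altA.astype(float) * refB).sum()
    den = (nA.astype(float) * nB).sum()
    return DiversityEstimate("dxy", float(num), float(den), sub.n_sites)


def fst_between(
    table: SiteTable, demeA, demeB,
    estimator: str = "weir-cockerham", min_presence: float = 0.5,
) -> FstEstimate:
    """Pairwise F_ST as a ratio of summed per-site variance components.

    ``estimator`` is ``"weir-cockerham"`` (1984 two-population components,
    the default) or ``"hudson"`` (Bhatia et al. ratio-of-averages form).
    Monomorphic sites and sites with fewer than two genotyped individuals
    in either deme contribute nothing.
    """
    if estimator not in ("weir-cockerham", "hudson"):
        raise ValueError(f"unknown F_ST estimator: {estimator!r}")
    demeA, demeB = list(demeA), list(demeB)
    sub = filter_site_presence(table, min_presence, demeA)
    sub = filter_site_presence(sub, min_presence, demeB)
    ia = sub.sample_indices(demeA)
    ib = sub.sample_indices(demeB)

    gA = sub.genotypes[:, ia]
    gB = sub.genotypes[:, ib]
    n1 = (gA >= 0).sum(axis=1).astype(float)  # diploid counts
    n2 = (gB >= 0).sum(axis=1).astype(float)
    alt1 = np.where(gA >= 0, gA, 0).sum(axis=1).astype(float)
    alt2 = np.where(gB >= 0, gB, 0).sum(axis=1).astype(float)
    usable = (n1 >= 2) & (n2 >= 2) & sub.is_variant
    # polymorphic across the two demes together
    tot_alt = alt1 + alt2
    tot_lin = 2 * (n1 + n2)
    usable &= (tot_alt > 0) & (tot_alt < tot_lin)
    if not usable.any():
        return FstEstimate(estimator, 0.0, 0.0,
                           0.0 if estimator == "weir-cockerham" else None, 0)
    n1, n2 = n1[usable], n2[usable]
    p1 = alt1[usable] / (2 * n1)
    p2 = alt2[usable] / (2 * n2)

    if estimator == "hudson":
        m1, m2 = 2 * n1, 2 * n2  # haploid sample sizes
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (m1 - 1)
               - p2 * (1 - p2) / (m2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return FstEstimate("hudson", float(num.sum()), float(den.sum()),
                           None, int(usable.sum()))

    h1 = (gA[usable] == 1).sum(axis=1) / n1  # observed heterozygosity
    h2 = (gB[usable] == 1).sum(axis=1) / n2
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return FstEstimate("weir-cockerham", float(a.sum()), float(b.sum()),
                       float(c.sum()), int(usable.sum()))


def count_site_classes(
    table: SiteTable, demes: dict, min_presence: float = 0.5
) -> list[DemeSummary]:
    """Per-deme totals of genotyped, polymorphic and private sites.

    ``demes`` maps deme id to its sample names. A site is private to a deme
    when it is polymorphic there and monomorphic in every other deme.
    Demes with fewer than five individuals are flagged ``excluded``.
    """
    ids = list(demes)
    poly = {}
    present = {}
    for d in ids:
        idx = table.sample_indices(demes[d])
        n_called, n_lin, alt = _deme_counts(table, idx)
        present[d] = n_called > 0
        poly[d] = (alt > 0) & (alt < n_lin)
    out = []
    for d in ids:
        others = [o for o in ids if o != d]
        if others:
            mono_elsewhere = np.ones(table.n_sites, dtype=bool)
            for o in others:
                mono_elsewhere &= ~poly[o]
            private = poly[d] & mono_elsewhere
        else:
            private = poly[d]
        pi = pi_within(table, demes[d], min_presence) \
            if len(demes[d]) >= 2 else \
            DiversityEstimate("pi", 0.0, 0.0, 0)
        out.append(DemeSummary(
            deme_id=str(d),
            n_individuals=len(demes[d]),
            total_sites=int(present[d].sum()),
            polymorphic_sites=int(poly[d].sum()),
            private_sites=int(private.sum()),
            pi=pi,
            excluded=len(demes[d]) < 5,
        ))
    return out


def welch_t(groupA, groupB) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided)."""
    a = np.asarray(list(groupA), dtype=float)
    b = np.asarray(list(groupB), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
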