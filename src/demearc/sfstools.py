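"""Folded site-frequency spectra with hypergeometric projection.

Spectra are built from biallelic variants (one per locus) by projecting each
site's minor-allele count down to a fixed number of haploid lineages
``m = 2 * projection_individuals`` via the hypergeometric expectation, which
tolerates missing genotypes: a site genotyped in ``n >= m`` lineages with
``d`` copies of the minor allele contributes the expected (fractional)
spectrum of all ``C(n, m)`` subsamples. Projected counts are kept as reals.

Folding conventions (ancestral states are unknown):

* 1-D: entry ``j`` (j < m/2) collects unfolded ``j`` and ``m - j``; the
  central entry ``m/2`` keeps its own mass once. Entry 0 is the
  monomorphic-after-projection class, recorded but masked by default.
* 2-D: cells ``(i, j)`` and ``(m1 - i, m2 - j)`` are combined into the
  member with the smaller total count ``i + j`` (ties broken toward the
  smaller ``i``; the self-symmetric centre keeps its own mass once).
  Corner cells ``(0, 0)`` and ``(m1, m2)`` are masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sitetable import SiteTable

__all__ = [
    "FoldedSFS",
    "JointFoldedSFS",
    "EligibilityReport",
    "site_allele_counts",
    "project_site",
    "build_folded_sfs",
    "build_joint_folded_sfs",
    "choose_projection",
    "check_eligibility",
    "fold_1d",
    "fold_2d",
    "write_sfs",
    "read_sfs",
]


# ---------------------------------------------------------------------------
# folding primitives (shared with the expected-SFS engines)


def fold_1d(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum of length m+1 to length m//2 + 1."""
    m = len(unfolded) - 1
    half = m // 2
    folded = np.zeros(half + 1)
    for j in range(half + 1):
        partner = m - j
        if partner == j:
            folded[j] = unfolded[j]
        else:
            folded[j] = unfolded[j] + unfolded[partner]
    return folded


_FOLD2D_CACHE: dict = {}


def _fold_2d_maps(shape):
    """Cached (kept mask, partner row/col indices) for a grid shape."""
    if shape not in _FOLD2D_CACHE:
        m1, m2 = shape[0] - 1, shape[1] - 1
        i, j = np.meshgrid(np.arange(m1 + 1), np.arange(m2 + 1),
                           indexing="ij")
        pi, pj = m1 - i, m2 - j
        self_sym = (i == pi) & (j == pj)
        s, ps = i + j, pi + pj
        kept = self_sym | (s < ps) | ((s == ps) & (i < pi))
        _FOLD2D_CACHE[shape] = (kept, self_sym, pi, pj)
    return _FOLD2D_CACHE[shape]


def fold_2d(unfolded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jointly fold a (m1+1, m2+1) grid about the global minor allele.

    Returns ``(folded, kept)`` where ``kept`` marks the cells that carry
    mass after folding (the complement is structurally zero). The
    self-symmetric centre cell keeps its own mass once.
    """
    kept, self_sym, pi, pj = _fold_2d_maps(unfolded.shape)
    partner = unfolded[pi, pj]
    folded = np.where(kept, unfolded + np.where(self_sym, 0.0, partner), 0.0)
    return folded, kept.copy()


def corner_mask(shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, 0] = True
    mask[-1, -1] = True
    return mask


@dataclass
class FoldedSFS:
    """Folded 1-D spectrum over ``0 .. m/2`` minor-allele-count classes."""

    counts: np.ndarray
    n_lineages: int
    monomorphic_masked: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_lineages % 2 or self.n_lineages <= 0:
            raise ValueError("n_lineages must be an even positive integer")
        if len(self.counts) != self.n_lineages // 2 + 1:
            raise ValueError("counts must have length n_lineages // 2 + 1")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def mask(self) -> np.ndarray:
        """True for entries excluded from likelihood sums."""
        mask = np.zeros(len(self.counts), dtype=bool)
        if self.monomorphic_masked:
            mask[0] = True
        return mask

    @property
    def segregating_mass(self) -> float:
        return float(self.counts[~self.mask].sum())


@dataclass
class JointFoldedSFS:
    """Jointly folded 2-D spectrum on the (m1+1, m2+1) grid."""

    counts: np.ndarray
    n1_lineages: int
    n2_lineages: int
    kept: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = (self.n1_lineages + 1, self.n2_lineages + 1)
        if self.counts.shape != expected:
            raise ValueError(f"counts must have shape {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def mask(self) -> np.ndarray:
        """True for cells excluded from likelihood sums."""
        return ~self.kept | corner_mask(self.counts.shape)

    @property
    def segregating_mass(self) -> float:
        return float(self.counts[~self.mask].sum())


# ---------------------------------------------------------------------------
# site-level inputs


def site_allele_counts(
    table: SiteTable, demes, min_presence: float = 0.7
):
    """Per-site minor-allele counts and genotyped lineages per deme.

    ``demes`` is a list of one or two sample collections. Only variant sites
    genotyped in at least ``min_presence`` of the pooled individuals are
    kept. The minor allele is defined globally over the pooled demes; ties
    resolve to the ALT allele. Returns ``(minor, lineages)`` where each is a
    list (per deme) of integer arrays over the retained sites.
    """
    if len(demes) not in (1, 2):
        raise ValueError("site_allele_counts takes one or two demes")
    idx_sets = [table.sample_indices(list(d)) for d in demes]
    pooled = np.concatenate(idx_sets)
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("demes overlap")
    g = table.genotypes
    called_pool = g[:, pooled] >= 0
    threshold = math.ceil(min_presence * len(pooled))
    keep = (called_pool.sum(axis=1) >= threshold) & table.is_variant
    keep_idx = np.flatnonzero(keep)

    alt_pool = np.where(called_pool, g[:, pooled], 0).sum(axis=1)[keep_idx]
    lin_pool = 2 * called_pool.sum(axis=1)[keep_idx]
    # globally minor allele: ALT unless ALT is the majority
    minor_is_alt = alt_pool <= lin_pool - alt_pool

    minor, lineages = [], []
    for idx in idx_sets:
        sub = g[keep_idx][:, idx]
        called = sub >= 0
        n_lin = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        d = np.where(minor_is_alt, alt, n_lin - alt)
        minor.append(d.astype(np.int64))
        lineages.append(n_lin.astype(np.int64))
    return minor, lineages, keep_idx


def project_site(d: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of d-of-n down to m lineages.

    Entry ``j`` is ``C(d, j) C(n-d, m-j) / C(n, m)``; the vector sums to 1.
    """
    if m > n:
        raise ValueError(f"cannot project {n} lineages down to {m}")
    if not (0 <= d <= n):
        raise ValueError("need 0 <= d <= n")
    if m < 2:
        raise ValueError("projection size must be at least 2 lineages")
    j = np.arange(m + 1)
    return stats.hypergeom.pmf(j, n, d, m)


# ---------------------------------------------------------------------------
# spectrum construction


def _projection_matrix(pairs, m):
    """Accumulated projection vectors for unique (d, n) pairs."""
    out = np.zeros(m + 1)
    d_arr, n_arr = pairs
    uniq, counts = np.unique(
        np.stack([d_arr, n_arr], axis=1), axis=0, return_counts=True)
    for (d, n), c in zip(uniq, counts):
        out += c * project_site(int(d), int(n), m)
    return out


def build_folded_sfs(
    table: SiteTable, deme, projection_individuals: int,
    min_presence: float = 0.7, monomorphic_masked: bool = True,
) -> FoldedSFS:
    """Folded SFS for one deme, projected to ``2 * projection_individuals``.

    Sites with fewer genotyped lineages than the projection size are
    dropped (count recorded in provenance).
    """
    deme = list(deme)
    if len(deme) < projection_individuals:
        raise ValueError(
            f"deme has {len(deme)} individuals < projection "
            f"{projection_individuals}")
    m = 2 * projection_individuals
    (minor,), (lineages,), keep_idx = site_allele_counts(
        table, [deme], min_presence)
    ok = lineages >= m
    unfolded = np.zeros(m + 1)
    if ok.any():
        unfolded = _projection_matrix((minor[ok], lineages[ok]), m)
    folded = fold_1d(unfolded)
    return FoldedSFS(
        counts=folded,
        n_lineages=m,
        monomorphic_masked=monomorphic_masked,
        provenance={
            "projection_individuals": projection_individuals,
            "min_presence": min_presence,
            "n_sites_input": int(len(keep_idx)),
            "n_sites_used": int(ok.sum()),
            "n_sites_dropped_low_coverage": int((~ok).sum()),
        },
    )


def build_joint_folded_sfs(
    table: SiteTable, demeA, demeB, projection_individuals: int = 6,
    min_presence: float = 0.7,
) -> JointFoldedSFS:
    """Jointly folded 2-D SFS for a deme pair (default 6 individuals/deme)."""
    demeA, demeB = list(demeA), list(demeB)
    for d in (demeA, demeB):
        if len(d) < projection_individuals:
            raise ValueError(
                f"deme has {len(d)} individuals < projection "
                f"{projection_individuals}")
    m1 = m2 = 2 * projection_individuals
    (dA, dB), (nA, nB), keep_idx = site_allele_counts(
        table, [demeA, demeB], min_presence)
    ok = (nA >= m1) & (nB >= m2)
    unfolded = np.zeros((m1 + 1, m2 + 1))
    dA, dB, nA, nB = dA[ok], dB[ok], nA[ok], nB[ok]
    stacked = np.stack([dA, nA, dB, nB], axis=1)
    uniq, counts = (np.unique(stacked, axis=0, return_counts=True)
                    if stacked.size else (np.empty((0, 4), int), np.empty(0)))
    for (da, na, db, nb), c in zip(uniq, counts):
        vA = project_site(int(da), int(na), m1)
        vB = project_site(int(db), int(nb), m2)
        unfolded += c * np.outer(vA, vB)
    folded, kept = fold_2d(unfolded)
    return JointFoldedSFS(
        counts=folded,
        n1_lineages=m1,
        n2_lineages=m2,
        kept=kept,
        provenance={
            "projection_individuals": projection_individuals,
            "min_presence": min_presence,
            "n_sites_input": int(len(keep_idx)),
            "n_sites_used": int(ok.sum()),
            "n_sites_dropped_low_coverage": int((~ok).sum()),
        },
    )


def choose_projection(
    table: SiteTable, deme, candidates=(5, 6, 7), min_presence: float = 0.7
) -> FoldedSFS:
    """Pick the projection size (in individuals) retaining the most
    segregating mass, among candidates not exceeding the deme size."""
    deme = list(deme)
    feasible = [c for c in candidates if c <= len(deme)]
    if not feasible:
        raise ValueError(
            f"deme of {len(deme)} individuals supports none of the "
            f"candidate projections {candidates}")
    best = None
    for c in feasible:
        sfs = build_folded_sfs(table, deme, c, min_presence)
        if best is None or sfs.segregating_mass > best.segregating_mass:
            best = sfs
    best.provenance["projection_candidates"] = list(feasible)
    return best


# ---------------------------------------------------------------------------
# eligibility


@dataclass(frozen=True)
class EligibilityReport:
    eligible: bool
    reasons: tuple[str, ...]
    variant_counts: tuple[float, ...]


def check_eligibility(
    sfs, n_individuals, min_individuals: int = 7, min_variants: int = 2000
) -> EligibilityReport:
    """Apply the analysis eligibility rules.

    Every deme needs at least ``min_individuals`` sampled individuals; deme
    pairs additionally need at least ``min_variants`` usable variants per
    deme (measured after thinning, presence filtering and projection).
    ``n_individuals`` is an int (single deme) or pair of ints.
    """
    reasons = []
    if isinstance(n_individuals, int):
        n_individuals = (n_individuals,)
    else:
        n_individuals = tuple(n_individuals)
    for i, n in enumerate(n_individuals, start=1):
        if n < min_individuals:
            reasons.append(
                f"deme {i} has {n} sampled individuals "
                f"(< {min_individuals})")
    if isinstance(sfs, JointFoldedSFS):
        per_deme = float(sfs.provenance.get("n_sites_used", sfs.segregating_mass))
        counts = (per_deme, per_deme)
        for i, c in enumerate(counts, start=1):
            if c < min_variants:
                reasons.append(
                    f"deme {i} has {c:g} usable variants (< {min_variants})")
    else:
        counts = (float(sfs.provenance.get(
            "n_sites_used", sfs.segregating_mass)),)
    return EligibilityReport(not reasons, tuple(reasons), counts)


# ---------------------------------------------------------------------------
# dadi-compatible flat text I/O


def write_sfs(sfs, path) -> None:
    """Write a (joint) folded spectrum in dadi flat-text layout.

    Header: dimensions and the word 'folded'; then the row-major counts over
    the full unfolded-shape grid (structurally empty cells as 0); then a
    0/1 mask row (1 = masked)."""
    with open(path, "w") as fh:
        if isinstance(sfs, JointFoldedSFS):
            fh.write(f"{sfs.n1_lineages + 1} {sfs.n2_lineages + 1} folded\n")
            fh.write(" ".join(f"{v:.10g}" for v in sfs.counts.ravel()) + "\n")
            fh.write(" ".join(
                str(int(v)) for v in sfs.mask.ravel().astype(int)) + "\n")
        else:
            full = np.zeros(sfs.n_lineages + 1)
            half = sfs.n_lineages // 2
            full[: half + 1] = sfs.counts
            mask = np.ones(sfs.n_lineages + 1, dtype=int)
            mask[: half + 1] = sfs.mask.astype(int)
            fh.write(f"{sfs.n_lineages + 1} folded\n")
            fh.write(" ".join(f"{v:.10g}" for v in full) + "\n")
            fh.write(" ".join(str(v) for v in mask) + "\n")


def read_sfs(path):
    """Read a spectrum written by :func:`write_sfs`."""
    with open(path) as fh:
        header = fh.readline().split()
        counts = np.array([float(x) for x in fh.readline().split()])
        mask = np.array([int(x) for x in fh.readline().split()], dtype=bool)
    dims = [int(x) for x in header if x.isdigit()]
    if len(dims) == 2:
        shape = (dims[0], dims[1])
        counts = counts.reshape(shape)
        # the kept pattern is structural (depends only on the shape)
        _, kept = fold_2d(np.zeros(shape))
        return JointFoldedSFS(
            counts=counts, n1_lineages=dims[0] - 1, n2_lineages=dims[1] - 1,
            kept=kept, provenance={"source": str(path)})
    m = dims[0] - 1
    half = m // 2
    return FoldedSFS(
        counts=counts[: half + 1], n_lineages=m,
        monomorphic_masked=bool(mask[0]),
        provenance={"source": str(path)})


def sfs_to_long_table(sfs):
    """Tab-separated long format (entry indices, count, masked flag)."""
    import pandas as pd

    if isinstance(sfs, JointFoldedSFS):
        i, j = np.meshgrid(
            np.arange(sfs.n1_lineages + 1), np.arange(sfs.n2_lineages + 1),
            indexing="ij")
        return pd.DataFrame({
            "minor_count_deme1": i.ravel(),
            "minor_count_deme2": j.ravel(),
            "count": sfs.counts.ravel(),
            "masked": sfs.mask.ravel().astype(int),
        })
    return pd.DataFrame({
        "minor_count": np.arange(len(sfs.counts)),
        "count": sfs.counts,
        "masked": sfs.mask.astype(int),
    })
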