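"""Genotype tables holding variant *and* invariant sites.

The central container is :class:`SiteTable`: a dense matrix of diploid
genotype calls over RAD-style loci, keeping invariant sites alongside
biallelic variants so that downstream diversity statistics can form proper
ratio-of-sums estimates (pairwise differences over pairwise comparisons).
Genotypes are stored as alternate-allele dosage (0, 1, 2; -1 = missing),
matching VCF ``GT`` semantics for a biallelic site. Per-genotype sequencing
depth (``DP``) is carried as a parallel integer matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SiteTable", "SampleMetadata", "read_vcf", "write_vcf"]

MISSING = -1

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class SampleMetadata:
    """Sample -> deme -> island -> habitat assignment (the popmap).

    Stored as a DataFrame with columns ``sample``, ``deme``, ``island``,
    ``habitat``; written to disk as 4-column tab-separated text without a
    header, one sample per line.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "deme", "island", "habitat"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"popmap missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            raise ValueError("popmap contains duplicated sample names")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def demes(self) -> list[str]:
        return list(pd.unique(self.table["deme"]))

    def samples_in_deme(self, deme: str) -> list[str]:
        sel = self.table.loc[self.table["deme"] == deme, "sample"]
        if sel.empty:
            raise KeyError(f"unknown deme: {deme!r}")
        return list(sel)

    def write(self, path) -> None:
        self.table[["sample", "deme", "island", "habitat"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def read(cls, path) -> "SampleMetadata":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["sample", "deme", "island", "habitat"], dtype=str,
        )
        return cls(df)


@dataclass
class SiteTable:
    """Dense per-site, per-sample genotype and depth matrix over RAD loci.

    Attributes
    ----------
    samples
        Ordered sample names (columns of the genotype matrix).
    locus_names, locus_lengths
        One entry per locus; loci are short (~121 bp) contigs.
    locus_index
        Per-site index into ``locus_names``.
    positions
        1-based position of each site within its locus.
    ref, alt
        Single-character alleles; ``alt == "."`` marks an invariant site.
    genotypes
        ``(n_sites, n_samples)`` int8 alternate-allele dosage; -1 = missing.
    depth
        Optional ``(n_sites, n_samples)`` int32 per-genotype DP.
    """

    samples: list[str]
    locus_names: np.ndarray
    locus_lengths: np.ndarray
    locus_index: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    n_multiallelic_dropped: int = 0

    def __post_init__(self) -> None:
        n_sites = len(self.positions)
        for name in ("locus_index", "ref", "alt"):
            if len(getattr(self, name)) != n_sites:
                raise ValueError(f"{name} length mismatch with positions")
        if self.genotypes.shape != (n_sites, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if self.depth is not None and self.depth.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape mismatch")

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def is_variant(self) -> np.ndarray:
        return self.alt != "."

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample not in table: {exc.args[0]!r}") from None

    # -- transformation ------------------------------------------------------

    def take_sites(self, mask_or_index) -> "SiteTable":
        """Return a new table restricted to the selected sites."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            locus_index=self.locus_index[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def copy(self) -> "SiteTable":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def allele_counts(self, sample_idx=None):
        """Per-site (ref_count, alt_count) over genotyped haploid lineages."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g >= 0
        n_lineages = 2 * called.sum(axis=1)
        alt_count = np.where(called, g, 0).sum(axis=1)
        return n_lineages - alt_count, alt_count


# ---------------------------------------------------------------------------
# VCF 4.2 I/O


def write_vcf(table: SiteTable, path) -> None:
    """Write a SiteTable as uncompressed VCF 4.2 text.

    Invariant sites are written with ``ALT=.``; genotypes as ``GT:DP`` (or
    plain ``GT`` when the table carries no depth). The writer is
    deterministic: identical tables produce byte-identical files.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=demearc\n")
    for name, length in zip(table.locus_names, table.locus_lengths):
        buf.write(f"##contig=<ID={name},length={int(length)}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    has_dp = table.depth is not None
    if has_dp:
        buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
        + "\n"
    )
    fmt = "GT:DP" if has_dp else "GT"
    order = np.lexsort((table.positions, table.locus_index))
    for i in order:
        chrom = table.locus_names[table.locus_index[i]]
        alt = table.alt[i]
        fields = [
            str(chrom), str(int(table.positions[i])), ".",
            str(table.ref[i]), str(alt), ".", "PASS", ".", fmt,
        ]
        row = table.genotypes[i]
        if has_dp:
            dp = table.depth[i]
            fields.extend(
                f"{_GT_STRINGS[int(g)]}:{int(d)}" for g, d in zip(row, dp)
            )
        else:
            fields.extend(_GT_STRINGS[int(g)] for g in row)
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vcf(path) -> SiteTable:
    """Read a (variant + invariant) VCF into a SiteTable using cyvcf2.

    Sites with more than one ALT allele are skipped with a count recorded on
    the returned table; half-calls are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    locus_names = np.asarray(vcf.seqnames, dtype=object)
    lens = vcf.seqlens
    locus_lengths = np.asarray(lens, dtype=np.int64)
    locus_lookup = {name: i for i, name in enumerate(locus_names)}

    loc_idx, pos, ref, alt, gts, dps = [], [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) > 1:
            n_multi += 1
            continue
        loc_idx.append(locus_lookup[v.CHROM])
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        # gts012: 0,1,2 dosage; 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            d = dp.reshape(-1).astype(np.int64)
            d[d < 0] = 0
            dps.append(d.astype(np.int32))
    n_sites = len(pos)
    genotypes = (
        np.vstack(gts) if n_sites else np.empty((0, len(samples)), np.int8)
    )
    depth = np.vstack(dps).astype(np.int32) if dps else None
    if depth is not None and depth.shape[0] != n_sites:
        raise ValueError("DP present for only a subset of records")
    return SiteTable(
        samples=samples,
        locus_names=locus_names,
        locus_lengths=locus_lengths,
        locus_index=np.asarray(loc_idx, dtype=np.int32),
        positions=np.asarray(pos, dtype=np.int32),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        genotypes=genotypes,
        depth=depth,
        n_multiallelic_dropped=n_multi,
    )
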