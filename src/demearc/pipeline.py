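"""End-to-end pipeline stages with flat key-value configs and manifests.

Each stage reads/writes plain-text artifacts (VCF, popmap, blacklist, TSV
tables, dadi-style SFS files) plus a JSON manifest recording inputs,
settings, the seed, package version and per-filter in/out site counts, so a
run can be audited and reproduced exactly. The stages are importable
functions; :mod:`demearc.cli` exposes them as subcommands.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import divstats, sfstools, synthdata
from .demofit import SearchConfig, run_isolation_analysis, run_persistence_analysis
from .sitefilter import (
    apply_blacklist,
    filter_mac,
    filter_site_presence,
    flag_overmerged,
    locus_theta,
    mask_by_depth,
    read_blacklist,
    recompute_alleles,
    thin_first_variant,
    write_blacklist,
)
from .sitetable import SampleMetadata, read_vcf, write_vcf

__all__ = [
    "RunConfig",
    "cmd_simulate",
    "cmd_filter",
    "cmd_stats",
    "cmd_sfs",
    "cmd_fit",
    "cmd_all",
]


class RunConfig(dict):
    """Flat key-value configuration (``key = value`` lines, ``#`` comments)."""

    @classmethod
    def read(cls, path) -> "RunConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            cfg[key] = value
        return cfg

    def get_int(self, key, default=None):
        return int(self[key]) if key in self else default

    def get_float(self, key, default=None):
        return float(self[key]) if key in self else default

    def get_bool(self, key, default=False):
        if key not in self:
            return default
        return str(self[key]).strip().lower() in ("1", "true", "yes", "on")

    def require(self, key):
        if key not in self:
            raise KeyError(f"config key {key!r} is required")
        return self[key]

    def seed(self) -> int:
        return int(self.require("rng_seed"))


def _write_manifest(outdir: Path, stage: str, payload: dict) -> Path:
    payload = {"stage": stage, "demearc_version": _version, **payload}
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def cmd_simulate(config: RunConfig, outdir) -> dict:
    """Generate a synthetic dataset; writes VCF + popmap + truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = config.require("model")
    params = {k[len("param."):]: float(v)
              for k, v in config.items() if k.startswith("param.")}
    sim_config = synthdata.SimulationConfig(
        n_loci=config.get_int("n_loci", 1000),
        samples_per_deme=tuple(
            int(x) for x in config.require("samples_per_deme").split(",")),
        locus_length_bp=config.get_int("locus_length_bp", 121),
        mu=config.get_float("mu", 2.8e-9),
        missing_rate=config.get_float("missing_rate", 0.35),
        locus_dropout_rate=config.get_float("locus_dropout_rate", 0.0),
        depth_mean_range=(config.get_float("depth_mean_min", 18.0),
                          config.get_float("depth_mean_max", 77.0)),
        depth_dispersion=config.get_float("depth_dispersion", 0.3),
        rng_seed=config.seed(),
    )
    data = synthdata.generate(model, params, sim_config)
    write_vcf(data.site_table, outdir / "simulated.vcf")
    synthdata.default_popmap(sim_config).write(outdir / "popmap.tsv")
    data.write_truth(outdir / "truth.txt")
    manifest = _write_manifest(outdir, "simulate", {
        "model": data.truth["model_id"],
        "params": data.truth["params"],
        "rng_seed": sim_config.rng_seed,
        "n_loci": sim_config.n_loci,
        "n_sites": data.site_table.n_sites,
        "n_variants": int(data.site_table.is_variant.sum()),
        "n_multiallelic_dropped": data.site_table.n_multiallelic_dropped,
        "outputs": ["simulated.vcf", "popmap.tsv", "truth.txt"],
    })
    return {"manifest": str(manifest)}


def cmd_filter(config: RunConfig, outdir) -> dict:
    """Depth masking, theta/blacklist locus removal, MAC + presence filters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_vcf(config.require("vcf"))
    counts = [("input", table.n_sites)]

    reports = {}
    if not config.get_bool("skip_depth_mask", False):
        table, depth_report = mask_by_depth(
            table,
            min_dp=config.get_int("min_dp", 5),
            high_percentile=config.get_float("high_dp_percentile", 0.975),
        )
        reports["depth_mask"] = {
            k: v for k, v in depth_report.items()
            if k != "thresholds_per_sample"}
    if config.get_bool("recompute_alleles", True):
        table = recompute_alleles(table)
    counts.append(("depth_mask", table.n_sites))

    blacklist = set()
    if "blacklist" in config:
        blacklist |= read_blacklist(config["blacklist"])
    if not config.get_bool("skip_theta_filter", False):
        records = locus_theta(table)
        flagged = flag_overmerged(
            records, config.get_float("theta_percentile", 0.995))
        blacklist |= flagged
        reports["theta_filter"] = {"n_flagged": len(flagged)}
    if blacklist:
        table, bl_report = apply_blacklist(table, blacklist)
        reports["blacklist"] = bl_report
        write_blacklist(blacklist, outdir / "blacklist_applied.txt")
    counts.append(("blacklist", table.n_sites))

    min_mac = config.get_int("min_mac", 0)
    if min_mac:
        table = filter_mac(table, min_mac)
    counts.append(("mac", table.n_sites))

    presence = config.get_float("min_presence", 0.0)
    if presence:
        table = filter_site_presence(table, presence, table.samples)
    counts.append(("presence", table.n_sites))

    if config.get_bool("thin", False):
        table = thin_first_variant(table)
    counts.append(("thin", table.n_sites))

    write_vcf(table, outdir / "filtered.vcf")
    pd.DataFrame(counts, columns=["filter", "sites_out"]).to_csv(
        outdir / "filter_counts.tsv", sep="\t", index=False)
    manifest = _write_manifest(outdir, "filter", {
        "input_vcf": str(config.require("vcf")),
        "settings": dict(config),
        "site_counts": counts,
        "reports": reports,
        "outputs": ["filtered.vcf", "filter_counts.tsv"],
    })
    return {"manifest": str(manifest), "n_sites": table.n_sites}


def _demes_from_popmap(popmap: SampleMetadata) -> dict:
    return {d: popmap.samples_in_deme(d) for d in popmap.demes}


def cmd_stats(config: RunConfig, outdir) -> dict:
    """Per-deme diversity summaries and pairwise D_XY / F_ST tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_vcf(config.require("vcf"))
    popmap = SampleMetadata.read(config.require("popmap"))
    demes = _demes_from_popmap(popmap)
    pi_presence = config.get_float("pi_min_presence", 0.5)
    pair_presence = config.get_float("pair_min_presence", 0.7)

    summaries = divstats.count_site_classes(table, demes, pi_presence)
    pd.DataFrame([{
        "deme": s.deme_id, "n_individuals": s.n_individuals,
        "total_sites": s.total_sites,
        "polymorphic_sites": s.polymorphic_sites,
        "private_sites": s.private_sites,
        "pi": s.pi.value, "pi_numerator": s.pi.numerator,
        "pi_denominator": s.pi.denominator,
        "excluded_lt5": s.excluded,
    } for s in summaries]).to_csv(
        outdir / "deme_summaries.tsv", sep="\t", index=False)

    rows = []
    ids = list(demes)
    estimator = config.get("fst_estimator", "weir-cockerham")
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dxy = divstats.dxy_between(table, demes[a], demes[b], pair_presence)
            fst = divstats.fst_between(
                table, demes[a], demes[b], estimator, pair_presence)
            rows.append({
                "deme1": a, "deme2": b,
                "dxy": dxy.value, "dxy_numerator": dxy.numerator,
                "dxy_denominator": dxy.denominator,
                "fst": fst.value, "fst_estimator": estimator,
            })
    pd.DataFrame(rows).to_csv(outdir / "pairwise_stats.tsv",
                              sep="\t", index=False)
    manifest = _write_manifest(outdir, "stats", {
        "input_vcf": str(config.require("vcf")),
        "popmap": str(config.require("popmap")),
        "settings": dict(config),
        "n_demes": len(demes),
        "outputs": ["deme_summaries.tsv", "pairwise_stats.tsv"],
    })
    return {"manifest": str(manifest)}


def cmd_sfs(config: RunConfig, outdir) -> dict:
    """Folded SFS per deme and joint SFS per deme pair (dadi text files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_vcf(config.require("vcf"))
    popmap = SampleMetadata.read(config.require("popmap"))
    demes = _demes_from_popmap(popmap)
    presence = config.get_float("sfs_min_presence", 0.7)
    thinned = thin_first_variant(table)
    outputs = []
    for d, samples in demes.items():
        if len(samples) < 5:
            continue
        sfs = sfstools.choose_projection(thinned, samples, (5, 6, 7), presence)
        path = outdir / f"sfs_{d}.txt"
        sfstools.write_sfs(sfs, path)
        outputs.append(path.name)
    ids = [d for d in demes if len(demes[d]) >= 6]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            jsfs = sfstools.build_joint_folded_sfs(
                thinned, demes[a], demes[b], 6, presence)
            path = outdir / f"jsfs_{a}_{b}.txt"
            sfstools.write_sfs(jsfs, path)
            outputs.append(path.name)
    manifest = _write_manifest(outdir, "sfs", {
        "input_vcf": str(config.require("vcf")),
        "settings": dict(config),
        "outputs": outputs,
    })
    return {"manifest": str(manifest)}


def _search_config(config: RunConfig) -> SearchConfig:
    base = SearchConfig()
    return SearchConfig(
        n_replicates=config.get_int("fit_replicates", base.n_replicates),
        n_loops=config.get_int("fit_loops", base.n_loops),
        sims_per_evaluation=config.get_int(
            "sims_per_evaluation", base.sims_per_evaluation),
        n_scan=config.get_int("fit_scan", base.n_scan),
        golden_iters=config.get_int("fit_golden_iters", base.golden_iters),
        final_sims=config.get_int("fit_final_sims", 0) or None,
        rng_seed=config.seed(),
    )


def cmd_fit(config: RunConfig, outdir, mode: str) -> dict:
    """Fit the two-deme (``mode='isolation'``) or single-deme
    (``mode='persistence'``) model set and write selection tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_vcf(config.require("vcf"))
    popmap = SampleMetadata.read(config.require("popmap"))
    demes = _demes_from_popmap(popmap)
    mu = config.get_float("mu", 2.8e-9)
    search = _search_config(config)

    outputs = []
    long_rows = []
    if mode == "isolation":
        ids = list(demes)
        if len(ids) != 2:
            raise ValueError(
                f"isolation fit needs a popmap with exactly 2 demes, "
                f"found {len(ids)}")
        result = run_isolation_analysis(table, demes, mu, search)
        cases = {f"{ids[0]}-{ids[1]}": result}
    elif mode == "persistence":
        cases = {}
        for d, samples in demes.items():
            cases[d] = run_persistence_analysis(table, d, samples, mu, search)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    for case, result in cases.items():
        path = outdir / f"selection_{mode}_{case}.tsv"
        result.selection.to_csv(path, sep="\t", index=False)
        outputs.append(path.name)
        for _, r in result.selection.iterrows():
            long_rows.append({"case": case, "model": r["model"],
                              "AIC_weight": r["AIC_weight"]})
    pd.DataFrame(long_rows).to_csv(
        outdir / f"aic_weights_{mode}_long.tsv", sep="\t", index=False)
    outputs.append(f"aic_weights_{mode}_long.tsv")
    manifest = _write_manifest(outdir, f"fit_{mode}", {
        "input_vcf": str(config.require("vcf")),
        "settings": dict(config),
        "rng_seed": search.rng_seed,
        "best_models": {case: r.best_model for case, r in cases.items()},
        "outputs": outputs,
    })
    return {"manifest": str(manifest),
            "best_models": {case: r.best_model for case, r in cases.items()}}


def cmd_all(config: RunConfig, outdir) -> dict:
    """simulate -> filter -> stats -> sfs -> fit, chained on one config."""
    outdir = Path(outdir)
    results = {"simulate": cmd_simulate(config, outdir)}
    chained = RunConfig(config)
    chained["vcf"] = str(outdir / "simulated.vcf")
    chained["popmap"] = str(outdir / "popmap.tsv")
    results["filter"] = cmd_filter(chained, outdir)
    chained["vcf"] = str(outdir / "filtered.vcf")
    results["stats"] = cmd_stats(chained, outdir)
    results["sfs"] = cmd_sfs(chained, outdir)
    n_demes = len(config.require("samples_per_deme").split(","))
    mode = "isolation" if n_demes == 2 else "persistence"
    results["fit"] = cmd_fit(chained, outdir, mode)
    return results
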