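"""Composite-likelihood fitting and AIC model selection on folded spectra.

Each demographic model is fitted to an observed (joint) folded SFS by
maximizing the composite log-likelihood

    lnL = sum over unmasked entries of  observed_count * ln(expected_prop)

where the expected proportions come from the simulation engines
(:mod:`demearc.engines`), conditioned on polymorphism. One contemporary
deme size is fixed at ``Ne = pi / (4 mu)`` so that the remaining parameters
are identifiable without invariant sites.

The optimizer is a multi-start cyclic conditional-maximization: each free
parameter in turn is maximized by bounded golden-section search on its
(log-transformed) box, cycling until the loop gain falls below a tolerance
or a loop cap is reached. Within a replicate the simulation engine reuses a
fixed seed (common random numbers), making the objective a deterministic
function of the parameters. Models are compared through AIC differences,
relative likelihoods and AIC weights.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import divstats, sfstools
from .engines import expected_sfs
from .models import (
    SINGLE_DEME_MODELS,
    TWO_DEME_MODELS,
    FreeParam,
    get_model,
    validate_params,
)
from .sfstools import FoldedSFS, JointFoldedSFS, check_eligibility
from .sitefilter import thin_first_variant
from .sitetable import SiteTable

__all__ = [
    "NeScaling",
    "ne_from_pi",
    "composite_loglik",
    "SearchConfig",
    "FitResult",
    "fit_model",
    "aic",
    "model_selection",
    "IneligibleError",
    "run_isolation_analysis",
    "run_persistence_analysis",
    "AnalysisResult",
    "selection_long_table",
]


class IneligibleError(ValueError):
    """The deme or pair fails the analysis eligibility rules."""


@dataclass(frozen=True)
class NeScaling:
    """Fixed contemporary effective size from nucleotide diversity."""

    pi_hat: float
    mu: float

    @property
    def fixed_ne(self) -> float:
        return self.pi_hat / (4.0 * self.mu)


def ne_from_pi(pi_hat: float, mu: float) -> NeScaling:
    """Ne = theta / (4 mu), approximating theta by pi."""
    if not (pi_hat > 0 and mu > 0):
        raise ValueError("pi_hat and mu must be positive")
    return NeScaling(float(pi_hat), float(mu))


def composite_loglik(observed, expected: np.ndarray) -> float:
    """Natural-log composite likelihood over unmasked spectrum entries."""
    counts = np.asarray(observed.counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if counts.shape != expected.shape:
        raise ValueError(
            f"spectrum shape {counts.shape} != expected {expected.shape}")
    mask = observed.mask
    obs = counts[~mask]
    exp_p = expected[~mask]
    if obs.sum() <= 0:
        raise ValueError("observed spectrum has no unmasked mass")
    if np.any(exp_p <= 0):
        raise ValueError("expected proportions must be positive (apply floor)")
    return float((obs * np.log(exp_p)).sum())


def aic(lnl: float, k: int) -> float:
    """Akaike information criterion: 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * lnl


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the multi-start conditional-maximization search.

    ``n_scan`` random parameter draws seed each replicate's start (the best
    scanned point wins); ``final_sims`` (absolute; defaults to
    ``sims_per_evaluation * final_sims_factor``) controls the
    high-precision re-evaluation of the best replicate, which uses a seed
    common to every model fitted under the same configuration.
    """

    n_replicates: int = 20
    n_loops: int = 30
    sims_per_evaluation: int = 10_000
    n_scan: int = 0
    golden_iters: int = 8
    loop_tol: float = 0.01
    final_sims_factor: int = 4
    final_sims: int | None = None
    floor: float | None = None
    rng_seed: int = 0
    # line searches bracket the incumbent: full box on the first loop
    # (initial_bracket = 1), then half-widths shrink by bracket_decay per
    # loop, so late loops refine instead of re-scanning whole decades
    initial_bracket: float = 1.0
    bracket_decay: float = 0.4
    min_bracket: float = 0.01


@dataclass
class FitResult:
    model_id: str
    params: dict
    lnl: float
    k: int
    aic: float
    n_replicates: int
    sims_per_evaluation: int
    rng_seed: int
    replicate_lnls: list = field(default_factory=list)
    observed_fingerprint: str = ""
    delta_aic: float = math.nan
    relative_likelihood: float = math.nan
    aic_weight: float = math.nan


def _fingerprint(observed) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(observed.counts, dtype=float).tobytes())
    h.update(observed.mask.astype(np.uint8).tobytes())
    return h.hexdigest()[:16]


def _coordinate_boxes(free: tuple[FreeParam, ...]):
    """(lo, hi, is_log) optimizer box per free parameter."""
    boxes = []
    for p in free:
        use_log = p.hi / p.lo >= 10.0
        if use_log:
            boxes.append((math.log10(p.lo), math.log10(p.hi), True))
        else:
            boxes.append((p.lo, p.hi, False))
    return boxes


def _x_to_params(spec, x, boxes, fixed_ne) -> dict:
    free_values = {}
    for p, xi, (_, _, is_log) in zip(spec.free, x, boxes):
        free_values[p.name] = 10.0 ** xi if is_log else xi
    return spec.params_from_free(free_values, fixed_ne)


def _golden_max(f, a: float, b: float, iters: int):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def _params_to_x(spec, params: dict, boxes) -> np.ndarray:
    """Map natural parameters into (clipped) optimizer coordinates."""
    x = []
    for p, (lo, hi, is_log) in zip(spec.free, boxes):
        value = float(params[p.name])
        if p.kind == "ratio":
            value = value / float(params[p.ref])
        xi = math.log10(value) if is_log else value
        x.append(min(max(xi, lo), hi))
    return np.array(x)


def fit_model(
    observed, model, scaling: NeScaling,
    config: SearchConfig = SearchConfig(), warm_starts=None,
    finalize: bool = True,
) -> FitResult:
    """Fit one demographic model to an observed folded spectrum.

    Runs ``config.n_replicates`` random multi-starts (each preceded by
    ``config.n_scan`` random probes); within each replicate, coordinates
    are cycled with golden-section line searches under common random
    numbers. ``warm_starts`` (natural-parameter dicts, e.g. the solution of
    a nested model) are run as additional replicates. The best replicate is
    re-evaluated at high precision with the base seed, so likelihoods are
    directly comparable across models fitted under the same configuration.
    """
    spec = get_model(model)
    boxes = _coordinate_boxes(spec.free)
    fingerprint = _fingerprint(observed)

    # one engine seed for the whole fit (and for every model fitted under
    # the same config): common random numbers make the objective a
    # deterministic surface shared across replicates and models
    eng_seed = int(np.random.default_rng(
        [config.rng_seed, 11]).integers(1, 2**31 - 1))
    cache: dict = {}

    def objective(x):
        key = tuple(round(v, 12) for v in x)
        if key not in cache:
            params = _x_to_params(spec, x, boxes, scaling.fixed_ne)
            exp_p = expected_sfs(
                spec, params, observed,
                n_sims=config.sims_per_evaluation,
                rng_seed=eng_seed, floor=config.floor)
            cache[key] = composite_loglik(observed, exp_p)
        return cache[key]

    warm_x = [
        _params_to_x(spec, w, boxes) for w in (warm_starts or [])
    ]
    best_x, best_lnl = None, -math.inf
    replicate_lnls = []
    for rep in range(config.n_replicates + len(warm_x)):
        if rep < len(warm_x):
            x = warm_x[rep].copy()
            lnl = objective(x)
        else:
            rng = np.random.default_rng(
                [config.rng_seed, rep - len(warm_x), 11])
            x = np.array([rng.uniform(lo, hi) for lo, hi, _ in boxes])
            lnl = objective(x)
            for _ in range(config.n_scan):
                cand = np.array([rng.uniform(lo, hi) for lo, hi, _ in boxes])
                cand_lnl = objective(cand)
                if cand_lnl > lnl:
                    x, lnl = cand, cand_lnl
        for loop in range(config.n_loops):
            lnl_before = lnl
            for ci, (lo, hi, _) in enumerate(boxes):
                half = (hi - lo) * max(
                    config.initial_bracket * config.bracket_decay**loop,
                    config.min_bracket)
                a = max(lo, x[ci] - half)
                b = min(hi, x[ci] + half)

                def line(v, _ci=ci):
                    xv = x.copy()
                    xv[_ci] = v
                    return objective(xv)
                v_best, f_best = _golden_max(line, a, b, config.golden_iters)
                if f_best > lnl:
                    x[ci] = v_best
                    lnl = f_best
            if loop >= 2 and lnl - lnl_before < config.loop_tol:
                break
        replicate_lnls.append(lnl)
        if lnl > best_lnl:
            best_lnl, best_x = lnl, x.copy()

    if best_x is None:
        raise RuntimeError(f"no replicate converged for model {spec.model_id}")
    best_params = _x_to_params(spec, best_x, boxes, scaling.fixed_ne)
    validate_params(spec, best_params)
    if finalize:
        final_sims = config.final_sims or (
            config.sims_per_evaluation * config.final_sims_factor)
        final_lnl = composite_loglik(observed, expected_sfs(
            spec, best_params, observed, n_sims=final_sims,
            rng_seed=config.rng_seed, floor=config.floor))
    else:
        final_lnl = best_lnl  # search-stage likelihood (shared CRN seed)
    return FitResult(
        model_id=spec.model_id,
        params=best_params,
        lnl=final_lnl,
        k=spec.k,
        aic=aic(final_lnl, spec.k),
        n_replicates=config.n_replicates,
        sims_per_evaluation=config.sims_per_evaluation,
        rng_seed=config.rng_seed,
        replicate_lnls=replicate_lnls,
        observed_fingerprint=fingerprint,
    )


def model_selection(fits: list[FitResult]) -> pd.DataFrame:
    """Rescale AICs to delta-AIC, relative likelihood and AIC weight.

    All fits must concern the same observed spectrum. The fits are updated
    in place and a selection table (sorted by AIC) returned.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    prints = {f.observed_fingerprint for f in fits}
    if len(prints) != 1:
        raise ValueError("fits come from different observed spectra")
    aics = np.array([f.aic for f in fits])
    deltas = aics - aics.min()
    rel = np.exp(-deltas / 2.0)
    weights = rel / rel.sum()
    for f, d, r, w in zip(fits, deltas, rel, weights):
        f.delta_aic = float(d)
        f.relative_likelihood = float(r)
        f.aic_weight = float(w)
    rows = [{
        "model": f.model_id,
        "k": f.k,
        "lnL": f.lnl,
        "AIC": f.aic,
        "delta_AIC": f.delta_aic,
        "relative_likelihood": f.relative_likelihood,
        "AIC_weight": f.aic_weight,
    } for f in fits]
    return (pd.DataFrame(rows)
            .sort_values("AIC", ignore_index=True))


@dataclass
class AnalysisResult:
    """Selection table plus per-model fits and provenance for one case."""

    selection: pd.DataFrame
    fits: list[FitResult]
    scaling: NeScaling
    sfs: object
    pi: dict
    fixed_deme: str
    eligibility: sfstools.EligibilityReport

    @property
    def best_model(self) -> str:
        return str(self.selection.iloc[0]["model"])


def _map_two_deme_params(params: dict, target: str) -> dict:
    """Translate one two-deme model's solution into another's space."""
    out = {k: params[k] for k in ("N_DEME1", "N_DEME2", "N_ANC", "T_DIV")}
    spec = get_model(target)
    names = set(spec.param_names)
    if "MIG" in names:
        out["MIG"] = float(np.clip(params.get("MIG", 5e-7), 5e-7, 1e-2))
    if "T_INT" in names:
        lo, hi = (0.5, 0.9) if target == "ISO2" else (0.1, 0.5)
        ratio = params.get("T_INT", math.nan) / params["T_DIV"]
        if not (lo <= ratio <= hi):
            ratio = (lo + hi) / 2
        out["T_INT"] = ratio * out["T_DIV"]
    return out


def _cross_polish_two_deme(jsfs, scaling, config: SearchConfig, fits: dict):
    """Refit each model from every other model's mapped solution.

    Equalizes search effort across the model set: without this pass, models
    fitted later (with warm starts) receive strictly more optimization than
    the models they nest, biasing AIC comparisons toward complexity.
    """
    from dataclasses import replace as _dc_replace

    polish = _dc_replace(config, n_replicates=0, n_scan=0, n_loops=2,
                         initial_bracket=0.1)
    for target in TWO_DEME_MODELS:
        warms = [
            _map_two_deme_params(fits[src].params, target)
            for src in TWO_DEME_MODELS if src != target
        ]
        refit = fit_model(jsfs, target, scaling, polish,
                          warm_starts=warms, finalize=False)
        if refit.lnl > fits[target].lnl:
            fits[target] = refit


def _finalize_fits(observed, scaling, config: SearchConfig, fits: dict,
                   mapper=None):
    """Re-evaluate every model's best parameters at high precision with one
    common seed, making the likelihoods directly comparable.

    When a cross-model parameter ``mapper`` is given, every model is also
    evaluated at the overall-best model's mapped solution and keeps the
    better point: near-equivalent models (e.g. a migration model stuck at
    its migration floor) then score from the same optimum and differ by
    their AIC penalty rather than by search-surface noise.
    """
    final_sims = config.final_sims or (
        config.sims_per_evaluation * config.final_sims_factor)

    def _final_lnl(model_id, params):
        return composite_loglik(observed, expected_sfs(
            get_model(model_id), params, observed, n_sims=final_sims,
            rng_seed=config.rng_seed, floor=config.floor))

    for model_id, fit in fits.items():
        fit.lnl = _final_lnl(model_id, fit.params)
    if mapper is not None:
        best_id = max(fits, key=lambda m: fits[m].lnl)
        for model_id, fit in fits.items():
            if model_id == best_id:
                continue
            mapped = mapper(fits[best_id].params, model_id)
            lnl = _final_lnl(model_id, mapped)
            if lnl > fit.lnl:
                fit.lnl = lnl
                fit.params = mapped
    for model_id, fit in fits.items():
        fit.aic = aic(fit.lnl, fit.k)


def run_isolation_analysis(
    table: SiteTable, demes: dict, mu: float,
    config: SearchConfig = SearchConfig(),
    projection_individuals: int = 6,
    pi_min_presence: float = 0.5,
    sfs_min_presence: float = 0.7,
) -> AnalysisResult:
    """Fit the four two-deme models (ISO1/ISO2/MIG1/MIG2) to a deme pair.

    ``demes`` maps the two deme names to their sample lists. The deme with
    the larger pi provides the fixed contemporary Ne (recorded as
    ``fixed_deme``); the jSFS is built from unlinked variants (first variant
    per locus) projected to ``projection_individuals`` per deme.
    """
    if len(demes) != 2:
        raise ValueError("isolation analysis needs exactly two demes")
    (name_a, samples_a), (name_b, samples_b) = demes.items()
    pi_a = divstats.pi_within(table, samples_a, pi_min_presence)
    pi_b = divstats.pi_within(table, samples_b, pi_min_presence)
    if pi_b.value > pi_a.value:
        name_a, name_b = name_b, name_a
        samples_a, samples_b = samples_b, samples_a
        pi_a, pi_b = pi_b, pi_a
    scaling = ne_from_pi(pi_a.value, mu)

    thinned = thin_first_variant(table)
    jsfs = sfstools.build_joint_folded_sfs(
        thinned, samples_a, samples_b, projection_individuals,
        sfs_min_presence)
    jsfs.provenance["fixed_deme"] = name_a
    eligibility = check_eligibility(jsfs, (len(samples_a), len(samples_b)))
    if not eligibility.eligible:
        raise IneligibleError("; ".join(eligibility.reasons))

    # method-of-moments starts from observed F_ST: under migration-drift
    # equilibrium F_ST ~ 1/(1 + 4Nm), under pure divergence F_ST ~ T/(T + 2N)
    ne = scaling.fixed_ne
    fst = divstats.fst_between(
        table, samples_a, samples_b, "hudson", sfs_min_presence).value
    fst = float(np.clip(fst if np.isfinite(fst) else 0.2, 0.01, 0.95))
    mig_moment = float(np.clip((1.0 / fst - 1.0) / (4.0 * ne), 5e-7, 1e-2))
    t_div_moment = float(np.clip(2.0 * ne * fst / (1.0 - fst), 10.0, 1e6))
    moment_iso = {"N_DEME1": ne, "N_DEME2": ne, "N_ANC": ne,
                  "T_DIV": t_div_moment}
    moment_mig = {"N_DEME1": ne, "N_DEME2": ne, "N_ANC": ne,
                  "T_DIV": float(np.clip(4.0 * ne, 10.0, 1e6)),
                  "MIG": mig_moment}

    # fit simpler models first and warm-start the models that nest them, so
    # a nested special case can never beat its host through optimizer luck
    fits = {}
    fits["ISO1"] = fit_model(jsfs, "ISO1", scaling, config,
                             warm_starts=[moment_iso], finalize=False)
    iso1 = fits["ISO1"].params
    near_zero_mig = {**iso1, "MIG": 5e-7}
    fits["MIG2"] = fit_model(
        jsfs, "MIG2", scaling, config,
        warm_starts=[near_zero_mig, moment_mig],
        finalize=False)
    mig2 = fits["MIG2"].params
    from dataclasses import replace as _dc_replace
    nested_config = _dc_replace(
        config, n_replicates=min(config.n_replicates, 1))
    fits["ISO2"] = fit_model(
        jsfs, "ISO2", scaling, nested_config,
        warm_starts=[
            {**near_zero_mig, "T_INT": 0.7 * iso1["T_DIV"]},
            {**mig2, "T_INT": 0.5 * mig2["T_DIV"]},
        ], finalize=False)
    fits["MIG1"] = fit_model(
        jsfs, "MIG1", scaling, nested_config,
        warm_starts=[
            {**mig2, "T_INT": 0.5 * mig2["T_DIV"]},
            {**near_zero_mig, "T_INT": 0.3 * iso1["T_DIV"]},
        ], finalize=False)
    _cross_polish_two_deme(jsfs, scaling, config, fits)
    _finalize_fits(jsfs, scaling, config, fits,
                   mapper=_map_two_deme_params)
    fits = [fits[m] for m in TWO_DEME_MODELS]
    selection = model_selection(fits)
    return AnalysisResult(
        selection=selection, fits=fits, scaling=scaling, sfs=jsfs,
        pi={name_a: pi_a.value, name_b: pi_b.value},
        fixed_deme=name_a, eligibility=eligibility)


def run_persistence_analysis(
    table: SiteTable, deme_name: str, samples, mu: float,
    config: SearchConfig = SearchConfig(),
    projection_candidates=(5, 6, 7),
    pi_min_presence: float = 0.5,
    sfs_min_presence: float = 0.7,
) -> AnalysisResult:
    """Fit the four single-deme models (CONST/EXPAND/CONTRACT/BOTTLE).

    The folded SFS is projected to whichever of ``projection_candidates``
    (individuals) retains the most segregating mass; the contemporary Ne is
    fixed from the deme's pi.
    """
    samples = list(samples)
    pi = divstats.pi_within(table, samples, pi_min_presence)
    scaling = ne_from_pi(pi.value, mu)
    thinned = thin_first_variant(table)
    sfs = sfstools.choose_projection(
        thinned, samples, projection_candidates, sfs_min_presence)
    eligibility = check_eligibility(sfs, len(samples))
    if not eligibility.eligible:
        raise IneligibleError("; ".join(eligibility.reasons))
    fits = {}
    fits["CONST"] = fit_model(sfs, "CONST", scaling, config)
    const = fits["CONST"].params
    fits["EXPAND"] = fit_model(sfs, "EXPAND", scaling, config)
    fits["CONTRACT"] = fit_model(sfs, "CONTRACT", scaling, config)
    # a vanishingly short crash makes BOTTLE nest CONST: warm-start there
    fits["BOTTLE"] = fit_model(
        sfs, "BOTTLE", scaling, config,
        warm_starts=[{
            "N_DEME": const["N_DEME"], "N_ANC": const["N_DEME"],
            "N_BOT": 1e-2 * const["N_DEME"],
            "T_0": const["T_0"], "T_BOT": max(1.0, 1e-3 * const["T_0"]),
        }])
    fits = [fits[m] for m in SINGLE_DEME_MODELS]
    selection = model_selection(fits)
    return AnalysisResult(
        selection=selection, fits=fits, scaling=scaling, sfs=sfs,
        pi={deme_name: pi.value}, fixed_deme=deme_name,
        eligibility=eligibility)


def selection_long_table(results: dict) -> pd.DataFrame:
    """Heatmap-ready long table of AIC weights per (case, model)."""
    rows = []
    for case, result in results.items():
        for _, r in result.selection.iterrows():
            rows.append({
                "case": case, "model": r["model"],
                "AIC_weight": r["AIC_weight"],
            })
    return pd.DataFrame(rows)
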