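"""The eight demographic models and their parameter constraints.

Two-deme models (local population isolation): an ancestral population of
diploid effective size ``N_ANC`` splits ``T_DIV`` generations ago into two
demes of constant sizes ``N_DEME1`` and ``N_DEME2``. Gene flow, when present,
is a symmetric per-lineage backward migration probability ``MIG`` active over
a (backward-time) window:

========  ==========================  =================================
model id  gene-flow window            constraint on T_INT
========  ==========================  =================================
ISO1      none (complete isolation)   --
ISO2      [T_INT, T_DIV]              0.5*T_DIV <= T_INT <= 0.9*T_DIV
MIG1      [0, T_INT]                  0.1*T_DIV <= T_INT <= 0.5*T_DIV
MIG2      [0, T_DIV]                  --
========  ==========================  =================================

Any active migration rate must satisfy ``MIG >= 5e-7``.

Single-deme models (local population persistence): a deme of contemporary
size ``N_DEME`` undergoes one instantaneous resize to ``N_ANC`` at time
``T_0 <= 300,000`` generations:

* CONST    -- 0.9*N_DEME <= N_ANC <= 1.1*N_DEME (no meaningful change)
* EXPAND   -- N_ANC <= 1e-2*N_DEME (deme grew)
* CONTRACT -- N_ANC >= 1e2*N_DEME (deme shrank)
* BOTTLE   -- N_ANC = N_DEME, with an episodic crash to
  ``N_BOT <= 1e-2*N_DEME`` occupying ``[T_0, T_0 + T_BOT]`` backward in time.

All sizes are diploid effective sizes; all times are in generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "FreeParam",
    "ConstraintError",
    "MODELS",
    "TWO_DEME_MODELS",
    "SINGLE_DEME_MODELS",
    "get_model",
    "validate_params",
]

MIN_MIGRATION = 5e-7
MAX_EVENT_TIME = 300_000.0  # single-deme resize bound, generations


class ConstraintError(ValueError):
    """A parameter set violates a named model constraint."""


@dataclass(frozen=True)
class FreeParam:
    """A free parameter searched during fitting.

    ``kind`` selects the transform used by the optimizer:

    * ``log``   -- optimized as log10(value) within [lo, hi] (absolute units)
    * ``ratio`` -- value = ratio * reference parameter (``ref``); the ratio
      itself lives in [lo, hi] and is optimized on log10 scale unless the box
      spans less than one decade.
    """

    name: str
    kind: str
    lo: float
    hi: float
    ref: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """A demographic model: identifier, free parameters and constraints."""

    model_id: str
    description: str
    n_demes: int
    fixed_param: str  # contemporary size pinned at the Ne scaling value
    free: tuple[FreeParam, ...]
    constraints: tuple[tuple[str, str], ...] = ()  # (name, python expression)

    @property
    def k(self) -> int:
        """Number of estimated parameters (AIC penalty)."""
        return len(self.free)

    @property
    def param_names(self) -> list[str]:
        return [self.fixed_param] + [p.name for p in self.free]

    def validate(self, params: dict) -> dict:
        return validate_params(self, params)

    # -- natural-parameter assembly -----------------------------------------

    def params_from_free(self, free_values: dict, fixed_ne: float) -> dict:
        """Expand free-parameter values (ratios resolved) into full params."""
        params = {self.fixed_param: float(fixed_ne)}
        # two passes so ratio parameters can reference earlier ones
        for p in self.free:
            if p.kind == "log":
                params[p.name] = float(free_values[p.name])
        for p in self.free:
            if p.kind == "ratio":
                params[p.name] = float(free_values[p.name]) * params[p.ref]
        if self.model_id == "BOTTLE":
            params["N_ANC"] = params[self.fixed_param]
            # episodic event: at least one generation, at most 0.2 * T_0
            params["T_BOT"] = float(np.clip(
                params["T_BOT"], 1.0, 0.2 * params["T_0"]))
        return params


def _mk(model_id, description, n_demes, fixed, free, constraints=()):
    return ModelSpec(model_id, description, n_demes, fixed, tuple(free),
                     tuple(constraints))


_SIZE = (10.0, 1e7)
_TDIV = (10.0, 1e6)
_T0 = (10.0, MAX_EVENT_TIME)
# upper bound sits well inside the strong-migration saturation regime
# (4Nm >> 10 for any plausible deme size), where the jSFS no longer changes
_MIG = (MIN_MIGRATION, 1e-2)

MODELS: dict[str, ModelSpec] = {}

MODELS["ISO1"] = _mk(
    "ISO1", "complete isolation", 2, "N_DEME1",
    [FreeParam("N_DEME2", "log", *_SIZE),
     FreeParam("N_ANC", "log", *_SIZE),
     FreeParam("T_DIV", "log", *_TDIV)],
)
MODELS["ISO2"] = _mk(
    "ISO2", "contemporary isolation (early contact interrupted at T_INT)", 2,
    "N_DEME1",
    [FreeParam("N_DEME2", "log", *_SIZE),
     FreeParam("N_ANC", "log", *_SIZE),
     FreeParam("T_DIV", "log", *_TDIV),
     FreeParam("T_INT", "ratio", 0.5, 0.9, ref="T_DIV"),
     FreeParam("MIG", "log", *_MIG)],
    [("T_INT_range", "0.5 * T_DIV <= T_INT <= 0.9 * T_DIV"),
     ("MIG_minimum", f"MIG >= {MIN_MIGRATION}")],
)
MODELS["MIG1"] = _mk(
    "MIG1", "contemporary migration (recent contact only)", 2, "N_DEME1",
    [FreeParam("N_DEME2", "log", *_SIZE),
     FreeParam("N_ANC", "log", *_SIZE),
     FreeParam("T_DIV", "log", *_TDIV),
     FreeParam("T_INT", "ratio", 0.1, 0.5, ref="T_DIV"),
     FreeParam("MIG", "log", *_MIG)],
    [("T_INT_range", "0.1 * T_DIV <= T_INT <= 0.5 * T_DIV"),
     ("MIG_minimum", f"MIG >= {MIN_MIGRATION}")],
)
MODELS["MIG2"] = _mk(
    "MIG2", "continuous migration since divergence", 2, "N_DEME1",
    [FreeParam("N_DEME2", "log", *_SIZE),
     FreeParam("N_ANC", "log", *_SIZE),
     FreeParam("T_DIV", "log", *_TDIV),
     FreeParam("MIG", "log", *_MIG)],
    [("MIG_minimum", f"MIG >= {MIN_MIGRATION}")],
)
MODELS["CONST"] = _mk(
    "CONST", "constant size (resize within +/-10%)", 1, "N_DEME",
    [FreeParam("N_ANC", "ratio", 0.9, 1.1, ref="N_DEME"),
     FreeParam("T_0", "log", *_T0)],
    [("N_ANC_range", "0.9 * N_DEME <= N_ANC <= 1.1 * N_DEME"),
     ("T_0_maximum", f"T_0 <= {MAX_EVENT_TIME:.0f}")],
)
MODELS["EXPAND"] = _mk(
    "EXPAND", "deme expansion (>= 100-fold growth at T_0)", 1, "N_DEME",
    [FreeParam("N_ANC", "ratio", 1e-5, 1e-2, ref="N_DEME"),
     FreeParam("T_0", "log", *_T0)],
    [("N_ANC_maximum", "N_ANC <= 1e-2 * N_DEME"),
     ("T_0_maximum", f"T_0 <= {MAX_EVENT_TIME:.0f}")],
)
MODELS["CONTRACT"] = _mk(
    "CONTRACT", "deme contraction (>= 100-fold decline at T_0)", 1, "N_DEME",
    [FreeParam("N_ANC", "ratio", 1e2, 1e5, ref="N_DEME"),
     FreeParam("T_0", "log", *_T0)],
    [("N_ANC_minimum", "N_ANC >= 1e2 * N_DEME"),
     ("T_0_maximum", f"T_0 <= {MAX_EVENT_TIME:.0f}")],
)
MODELS["BOTTLE"] = _mk(
    "BOTTLE", "episodic bottleneck (crash to N_BOT over [T_0, T_0+T_BOT])", 1,
    "N_DEME",
    [FreeParam("N_BOT", "ratio", 1e-5, 1e-2, ref="N_DEME"),
     FreeParam("T_0", "log", *_T0),
     FreeParam("T_BOT", "ratio", 1e-3, 0.2, ref="T_0")],
    [("N_BOT_maximum", "N_BOT <= 1e-2 * N_DEME"),
     ("N_ANC_pinned", "N_ANC == N_DEME"),
     ("T_0_maximum", f"T_0 <= {MAX_EVENT_TIME:.0f}"),
     ("T_BOT_range", "1 <= T_BOT <= 0.2 * T_0")],
)

# long descriptive aliases accepted in configs and file formats
_ALIASES = {
    "ISO1_complete_isolation": "ISO1",
    "ISO2_contemporary_isolation": "ISO2",
    "MIG1_contemporary_migration": "MIG1",
    "MIG2_continuous_migration": "MIG2",
}

TWO_DEME_MODELS = ("ISO1", "ISO2", "MIG1", "MIG2")
SINGLE_DEME_MODELS = ("CONST", "EXPAND", "CONTRACT", "BOTTLE")


def get_model(model_id) -> ModelSpec:
    if isinstance(model_id, ModelSpec):
        return model_id
    key = _ALIASES.get(model_id, model_id).upper()
    key = _ALIASES.get(key, key)
    if key not in MODELS:
        raise KeyError(
            f"unknown model {model_id!r}; known: {sorted(MODELS)}")
    return MODELS[key]


def _require(ok: bool, name: str, detail: str):
    if not ok:
        raise ConstraintError(f"constraint {name!r} violated: {detail}")


def validate_params(model: ModelSpec | str, params: dict) -> dict:
    """Check a natural-unit parameter map against the model's constraints.

    Returns the validated (float-coerced) parameter map; raises
    :class:`ConstraintError` naming the violated constraint otherwise.
    """
    model = get_model(model) if isinstance(model, str) else model
    p = {k: float(v) for k, v in params.items()}
    needed = set(model.param_names)
    if model.model_id == "BOTTLE":
        p.setdefault("N_ANC", p.get("N_DEME", np.nan))
        needed.add("N_ANC")
    if model.model_id == "ISO1":
        p.setdefault("MIG", 0.0)
    missing = sorted(needed - set(p))
    if missing:
        raise ConstraintError(f"missing parameters for {model.model_id}: {missing}")

    for name in needed:
        if name.startswith("N_"):
            _require(p[name] > 0, "positive_size", f"{name} = {p[name]}")
        elif name.startswith("T_"):
            _require(p[name] > 0, "positive_time", f"{name} = {p[name]}")

    mid = model.model_id
    if mid in ("ISO2", "MIG1", "MIG2"):
        _require(p["MIG"] >= MIN_MIGRATION, "MIG_minimum",
                 f"MIG = {p['MIG']:g} < {MIN_MIGRATION:g}")
    if mid == "ISO2":
        _require(0.5 * p["T_DIV"] <= p["T_INT"] <= 0.9 * p["T_DIV"],
                 "T_INT_range",
                 f"T_INT = {p['T_INT']:g} outside [0.5, 0.9] * T_DIV")
    if mid == "MIG1":
        _require(0.1 * p["T_DIV"] <= p["T_INT"] <= 0.5 * p["T_DIV"],
                 "T_INT_range",
                 f"T_INT = {p['T_INT']:g} outside [0.1, 0.5] * T_DIV")
    if mid in SINGLE_DEME_MODELS:
        _require(p["T_0"] <= MAX_EVENT_TIME, "T_0_maximum",
                 f"T_0 = {p['T_0']:g} > {MAX_EVENT_TIME:.0f}")
    if mid == "CONST":
        _require(0.9 * p["N_DEME"] <= p["N_ANC"] <= 1.1 * p["N_DEME"],
                 "N_ANC_range",
                 f"N_ANC = {p['N_ANC']:g} outside [0.9, 1.1] * N_DEME")
    if mid == "EXPAND":
        _require(p["N_ANC"] <= 1e-2 * p["N_DEME"], "N_ANC_maximum",
                 f"N_ANC = {p['N_ANC']:g} > 1e-2 * N_DEME")
    if mid == "CONTRACT":
        _require(p["N_ANC"] >= 1e2 * p["N_DEME"], "N_ANC_minimum",
                 f"N_ANC = {p['N_ANC']:g} < 1e2 * N_DEME")
    if mid == "BOTTLE":
        _require(abs(p["N_ANC"] - p["N_DEME"]) <= 1e-9 * p["N_DEME"],
                 "N_ANC_pinned", "BOTTLE requires N_ANC == N_DEME")
        _require(p["N_BOT"] <= 1e-2 * p["N_DEME"], "N_BOT_maximum",
                 f"N_BOT = {p['N_BOT']:g} > 1e-2 * N_DEME")
        _require(1.0 <= p["T_BOT"] <= 0.2 * p["T_0"], "T_BOT_range",
                 f"T_BOT = {p['T_BOT']:g} outside [1, 0.2 * T_0]")
    return p


# ---------------------------------------------------------------------------
# Canonical descriptions used by the simulation engines


def single_deme_epochs(model: ModelSpec | str, params: dict):
    """Piecewise-constant size history as (epoch start times, diploid sizes).

    Epoch 0 starts at time 0 (the present); times increase into the past.
    """
    model = get_model(model) if isinstance(model, str) else model
    p = validate_params(model, params)
    if model.model_id == "BOTTLE":
        starts = np.array([0.0, p["T_0"], p["T_0"] + p["T_BOT"]])
        sizes = np.array([p["N_DEME"], p["N_BOT"], p["N_ANC"]])
    else:
        starts = np.array([0.0, p["T_0"]])
        sizes = np.array([p["N_DEME"], p["N_ANC"]])
    return starts, sizes


def two_deme_layout(model: ModelSpec | str, params: dict):
    """(N1, N2, N_ANC, T_DIV, MIG, window_lo, window_hi) for the engines."""
    model = get_model(model) if isinstance(model, str) else model
    p = validate_params(model, params)
    mid = model.model_id
    if mid == "ISO1":
        mig, lo, hi = 0.0, 0.0, 0.0
    elif mid == "ISO2":
        mig, lo, hi = p["MIG"], p["T_INT"], p["T_DIV"]
    elif mid == "MIG1":
        mig, lo, hi = p["MIG"], 0.0, p["T_INT"]
    elif mid == "MIG2":
        mig, lo, hi = p["MIG"], 0.0, p["T_DIV"]
    else:
        raise ValueError(f"{mid} is not a two-deme model")
    return (p["N_DEME1"], p["N_DEME2"], p["N_ANC"], p["T_DIV"], mig, lo, hi)


def to_msprime_demography(model: ModelSpec | str, params: dict):
    """Build the msprime Demography for a model (used by the simulator)."""
    import msprime

    model = get_model(model) if isinstance(model, str) else model
    p = validate_params(model, params)
    dem = msprime.Demography()
    if model.n_demes == 2:
        n1, n2, na, tdiv, mig, lo, hi = two_deme_layout(model, p)
        dem.add_population(name="deme1", initial_size=n1)
        dem.add_population(name="deme2", initial_size=n2)
        dem.add_population(name="anc", initial_size=na)
        if mig > 0:
            if lo == 0.0:
                dem.set_symmetric_migration_rate(["deme1", "deme2"], mig)
                if hi < tdiv:
                    dem.add_symmetric_migration_rate_change(
                        time=hi, populations=["deme1", "deme2"], rate=0.0)
            else:
                dem.add_symmetric_migration_rate_change(
                    time=lo, populations=["deme1", "deme2"], rate=mig)
        dem.add_population_split(time=tdiv, derived=["deme1", "deme2"],
                                 ancestral="anc")
    else:
        starts, sizes = single_deme_epochs(model, p)
        dem.add_population(name="deme1", initial_size=sizes[0])
        for t, n in zip(starts[1:], sizes[1:]):
            dem.add_population_parameters_change(
                time=t, population="deme1", initial_size=n)
    dem.sort_events()
    return dem
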