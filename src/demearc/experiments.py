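"""Simulation-based model-class recovery experiments.

These are the package's calibration studies: datasets are generated under a
known demographic truth, pushed through the standard pipeline (missingness,
presence filtering, thinning, projection) and fitted with the full model
set; success means the *class* of the generating model — high vs. low
persistence for single demes, isolation vs. contact for deme pairs — takes
the top AIC weight.

The study conditions are fixed here, once, as module constants:

Persistence (single deme, natural units)
    N_DEME = 1e5 (the contemporary Ne implied by the dune-habitat
    nucleotide diversity pi ~ 0.0013 via Ne = pi/4mu at mu = 2.8e-9),
    10,000 loci x 121 bp (~2,000 usable variants per deme, matching the
    per-deme spectra of the empirical system), 8 diploid individuals, 10%
    random missingness. The bottleneck truth crashes to N_BOT = 1e-2*N_DEME
    for T_BOT = 1,000 generations starting T_0 = 20,000 generations ago —
    coalescent intensity 0.5 inside the crash, so a recoverable share of
    lineages survives into the deep ancestral phase.

Isolation (two demes, population-scaled units)
    N = 1,000 per deme with mu = 2.8e-7, preserving theta = 4*N*mu ~ 1.1e-3
    (the empirical dune-habitat diversity) at desk-scale simulation cost;
    the migration truth MIG = 1e-3 then corresponds to 4Nm = 4, i.e.
    F_ST ~ 0.2, matching the observed differentiation. 6,000 loci,
    8 + 8 diploids, 10% missingness. Both truths use T_DIV = 2,000
    (one coalescent unit): deep enough for a clean-split signature under
    complete isolation, and long enough under continuous migration (~2
    migration events per lineage) for the recurrent-migration signature --
    shared rare alleles carried by recent migrants -- to accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demofit import SearchConfig, run_isolation_analysis, run_persistence_analysis
from .synthdata import SimulationConfig, apply_missingness, simulate_dataset

__all__ = [
    "MODEL_CLASS",
    "PERSISTENCE_TRUTHS",
    "ISOLATION_TRUTHS",
    "persistence_dataset",
    "isolation_dataset",
    "persistence_recovery",
    "isolation_recovery",
    "PERSISTENCE_SEARCH",
    "ISOLATION_SEARCH",
]

MODEL_CLASS = {
    "CONST": "high-persistence",
    "EXPAND": "high-persistence",
    "CONTRACT": "low-persistence",
    "BOTTLE": "low-persistence",
    "ISO1": "isolation",
    "ISO2": "isolation",
    "MIG1": "contact",
    "MIG2": "contact",
}

# ---------------------------------------------------------------------------
# study conditions (fixed)

_PERSIST_N = 1e5
PERSISTENCE_TRUTHS = {
    "CONST": {"N_DEME": _PERSIST_N, "N_ANC": _PERSIST_N, "T_0": 20_000.0},
    "BOTTLE": {"N_DEME": _PERSIST_N, "N_ANC": _PERSIST_N,
               "N_BOT": 1e-2 * _PERSIST_N, "T_0": 20_000.0, "T_BOT": 1_000.0},
}
_PERSIST_MU = 2.8e-9
_PERSIST_LOCI = 10_000
_PERSIST_INDIVIDUALS = 8

_ISO_N = 1_000.0
ISOLATION_TRUTHS = {
    "ISO1": {"N_DEME1": _ISO_N, "N_DEME2": _ISO_N, "N_ANC": _ISO_N,
             "T_DIV": 2_000.0},
    "MIG2": {"N_DEME1": _ISO_N, "N_DEME2": _ISO_N, "N_ANC": _ISO_N,
             "T_DIV": 2_000.0, "MIG": 1e-3},
}
_ISO_MU = 2.8e-7
_ISO_LOCI = 6_000
_ISO_INDIVIDUALS = 8

_MISSING = 0.10

PERSISTENCE_SEARCH = SearchConfig(
    n_replicates=20, n_loops=30, sims_per_evaluation=10_000,
    golden_iters=6, loop_tol=0.15, final_sims=200_000, rng_seed=0)
ISOLATION_SEARCH = SearchConfig(
    n_replicates=2, n_scan=20, n_loops=5, sims_per_evaluation=1_000,
    golden_iters=5, loop_tol=0.3, final_sims=150_000, rng_seed=0)


def _derive_seed(base_seed: int, *salt) -> int:
    import zlib

    words = [zlib.crc32(str(s).encode()) for s in salt]
    return int(np.random.default_rng(
        [int(base_seed), *words]).integers(1, 2**31 - 1))


def persistence_dataset(truth_model: str, seed: int):
    """Generate one single-deme dataset under a persistence truth."""
    config = SimulationConfig(
        n_loci=_PERSIST_LOCI,
        samples_per_deme=(_PERSIST_INDIVIDUALS,),
        mu=_PERSIST_MU,
        missing_rate=_MISSING,
        rng_seed=_derive_seed(seed, "persist", truth_model),
    )
    data = simulate_dataset(truth_model, PERSISTENCE_TRUTHS[truth_model], config)
    return apply_missingness(
        data, _MISSING, 0.0, _derive_seed(seed, "persist-miss", truth_model))


def isolation_dataset(truth_model: str, seed: int):
    """Generate one deme-pair dataset under an isolation/contact truth."""
    config = SimulationConfig(
        n_loci=_ISO_LOCI,
        samples_per_deme=(_ISO_INDIVIDUALS, _ISO_INDIVIDUALS),
        mu=_ISO_MU,
        missing_rate=_MISSING,
        rng_seed=_derive_seed(seed, "iso", truth_model),
    )
    data = simulate_dataset(truth_model, ISOLATION_TRUTHS[truth_model], config)
    return apply_missingness(
        data, _MISSING, 0.0, _derive_seed(seed, "iso-miss", truth_model))


@dataclass
class RecoveryOutcome:
    truth_model: str
    seed: int
    best_model: str
    best_class: str
    correct_class: bool
    aic_weights: dict


def _outcome(truth_model, seed, result) -> RecoveryOutcome:
    best = result.best_model
    weights = dict(zip(result.selection["model"], result.selection["AIC_weight"]))
    return RecoveryOutcome(
        truth_model=truth_model,
        seed=seed,
        best_model=best,
        best_class=MODEL_CLASS[best],
        correct_class=MODEL_CLASS[best] == MODEL_CLASS[truth_model],
        aic_weights=weights,
    )


def persistence_recovery(
    truth_model: str, seeds, search: SearchConfig = PERSISTENCE_SEARCH
) -> pd.DataFrame:
    """Run the single-deme recovery experiment over the given seeds."""
    rows = []
    for seed in seeds:
        data = persistence_dataset(truth_model, seed)
        table = data.site_table
        cfg = SearchConfig(**{**search.__dict__,
                              "rng_seed": _derive_seed(seed, "fitp")})
        result = run_persistence_analysis(
            table, "deme1", table.samples, _PERSIST_MU, cfg)
        rows.append(_outcome(truth_model, seed, result).__dict__)
    return pd.DataFrame(rows)


def isolation_recovery(
    truth_model: str, seeds, search: SearchConfig = ISOLATION_SEARCH
) -> pd.DataFrame:
    """Run the two-deme recovery experiment over the given seeds."""
    rows = []
    for seed in seeds:
        data = isolation_dataset(truth_model, seed)
        table = data.site_table
        demes = {
            "deme1": [s for s in table.samples if s.startswith("deme1_")],
            "deme2": [s for s in table.samples if s.startswith("deme2_")],
        }
        cfg = SearchConfig(**{**search.__dict__,
                              "rng_seed": _derive_seed(seed, "fiti")})
        result = run_isolation_analysis(table, demes, _ISO_MU, cfg)
        rows.append(_outcome(truth_model, seed, result).__dict__)
    return pd.DataFrame(rows)
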