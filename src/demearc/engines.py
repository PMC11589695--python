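"""Simulation engines for expected folded spectra under demographic models.

Both engines target the same quantity a SNP-simulation engine estimates --
the expected proportion of polymorphic sites per (joint) folded frequency
class -- but accumulate *expected branch lengths* instead of Poisson mutation
draws, which removes the mutation-sampling noise from every likelihood
evaluation (the expectation is unchanged: under neutrality a site's chance
of carrying a variant subtended by a branch is proportional to the branch's
length).

Single-deme engine (piecewise-constant size history)
    Standard-coalescent interval variables are drawn once per replicate and
    mapped deterministically through the size history's cumulative
    coalescent intensity (a time rescaling), so the same random numbers are
    reused across parameter evaluations. The tree-shape factor is integrated
    out analytically: the expected number of branches subtending ``i`` of
    ``n`` leaves while ``k`` ancestral lineages remain is
    ``k * C(n-i-1, k-2) / C(n-1, k-1)``.

Two-deme engine (divergence with windowed symmetric migration)
    A numba-compiled structured-coalescent Gillespie simulation tracks, for
    every ancestral lineage, how many sampled lineages it subtends in each
    deme, and accumulates interval lengths into the joint unfolded grid.
    Replicate seeds are fixed, giving common random numbers across parameter
    evaluations within a fit replicate.

Both engines are cross-checked against msprime branch-mode allele frequency
spectra in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import comb

from .models import get_model, single_deme_epochs, two_deme_layout, validate_params
from .sfstools import FoldedSFS, JointFoldedSFS, fold_1d, fold_2d

__all__ = ["expected_sfs", "single_deme_branch_sfs", "two_deme_branch_jsfs"]


# ---------------------------------------------------------------------------
# single-deme engine


_STANDARD_CACHE: dict = {}


def _standard_event_times(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Cumulative standard-coalescent event times U (reps, n-1).

    Column j is the coalescent-intensity coordinate of the event taking
    ``n - j`` lineages to ``n - j - 1``.
    """
    key = (n, n_reps, seed)
    if key not in _STANDARD_CACHE:
        if len(_STANDARD_CACHE) > 64:
            _STANDARD_CACHE.clear()
        rng = np.random.default_rng(seed)
        levels = np.arange(n, 1, -1)
        rates = levels * (levels - 1) / 2.0
        intervals = rng.exponential(1.0, size=(n_reps, n - 1)) / rates
        _STANDARD_CACHE[key] = np.cumsum(intervals, axis=1)
    return _STANDARD_CACHE[key]


def _branch_count_matrix(n: int) -> np.ndarray:
    """E[# lineages subtending i leaves | k lineages remain]: (level, i)."""
    ks = np.arange(n, 1, -1)
    i = np.arange(1, n)
    e = np.zeros((n - 1, n - 1))
    for row, k in enumerate(ks):
        e[row] = k * comb(n - i - 1, k - 2) / comb(n - 1, k - 1)
    return e


def _intensity_inverse(u: np.ndarray, starts: np.ndarray, sizes: np.ndarray):
    """Map coalescent-intensity coordinates to generations.

    ``starts``/``sizes`` describe the piecewise-constant diploid size
    history (epoch start times, sizes); the intensity accumulates at rate
    ``1 / (2N)`` per generation.
    """
    widths = np.diff(starts)
    u_bounds = np.concatenate(
        [[0.0], np.cumsum(widths / (2.0 * sizes[:-1]))])
    epoch = np.searchsorted(u_bounds, u, side="right") - 1
    epoch = np.clip(epoch, 0, len(sizes) - 1)
    return starts[epoch] + (u - u_bounds[epoch]) * 2.0 * sizes[epoch]


def single_deme_branch_sfs(
    starts: np.ndarray, sizes: np.ndarray, n: int,
    n_sims: int, rng_seed: int,
) -> np.ndarray:
    """Expected unfolded branch-length SFS (length n+1; entries 1..n-1)."""
    U = _standard_event_times(n, n_sims, rng_seed)
    T = _intensity_inverse(U, np.asarray(starts, float), np.asarray(sizes, float))
    durations = np.diff(T, axis=1, prepend=0.0)
    d_bar = durations.mean(axis=0)
    xi = d_bar @ _branch_count_matrix(n)
    out = np.zeros(n + 1)
    out[1:n] = xi
    return out


# ---------------------------------------------------------------------------
# two-deme engine


@njit(cache=True)
def _two_deme_gillespie(n1, n2, N1, N2, NA, T_div, mig, mig_lo, mig_hi,
                        n_reps, seed):  # pragma: no cover - numba
    out = np.zeros((n1 + 1, n2 + 1))
    np.random.seed(seed)
    ntot = n1 + n2
    deme = np.empty(ntot, np.int64)
    dA = np.empty(ntot, np.int64)
    dB = np.empty(ntot, np.int64)
    for _ in range(n_reps):
        for i in range(n1):
            deme[i] = 0; dA[i] = 1; dB[i] = 0
        for i in range(n1, ntot):
            deme[i] = 1; dA[i] = 0; dB[i] = 1
        k = ntot
        kA = n1
        t = 0.0
        # phase 1: two demes until the split time (backwards: the merge)
        while k > 1 and t < T_div:
            kB = k - kA
            rA = kA * (kA - 1) / 2.0 / (2.0 * N1)
            rB = kB * (kB - 1) / 2.0 / (2.0 * N2)
            rM = mig * k if (mig > 0.0 and t >= mig_lo and t < mig_hi) else 0.0
            R = rA + rB + rM
            # nearest future rate boundary
            tb = T_div
            if mig > 0.0:
                if t < mig_lo and mig_lo < tb:
                    tb = mig_lo
                elif mig_lo <= t < mig_hi and mig_hi < tb:
                    tb = mig_hi
            if R <= 0.0:
                dt = tb - t
                event = False
            else:
                dt = np.random.exponential(1.0 / R)
                if t + dt > tb:
                    dt = tb - t
                    event = False
                else:
                    event = True
            for i in range(k):
                out[dA[i], dB[i]] += dt
            t += dt
            if not event:
                continue
            u = np.random.random() * R
            if u < rA + rB:
                d = 0 if u < rA else 1
                kd = kA if d == 0 else kB
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                ia = -1; ib = -1; c = 0
                for i in range(k):
                    if deme[i] == d:
                        if c == a:
                            ia = i
                        if c == b:
                            ib = i
                        c += 1
                dA[ia] += dA[ib]
                dB[ia] += dB[ib]
                deme[ib] = deme[k - 1]
                dA[ib] = dA[k - 1]
                dB[ib] = dB[k - 1]
                k -= 1
                if d == 0:
                    kA -= 1
            else:
                i = np.random.randint(k)
                if deme[i] == 0:
                    kA -= 1
                else:
                    kA += 1
                deme[i] = 1 - deme[i]
        # phase 2: one ancestral population (same random-stream consumption
        # as the general loop: exponential, event selector, pair indices)
        while k > 1:
            R = k * (k - 1) / 2.0 / (2.0 * NA)
            dt = np.random.exponential(1.0 / R)
            for i in range(k):
                out[dA[i], dB[i]] += dt
            t += dt
            np.random.random()  # event selector (always a coalescence here)
            a = np.random.randint(k)
            b = np.random.randint(k - 1)
            if b >= a:
                b += 1
            dA[a] += dA[b]
            dB[a] += dB[b]
            dA[b] = dA[k - 1]
            dB[b] = dB[k - 1]
            k -= 1
    out[0, 0] = 0.0
    out[n1, n2] = 0.0
    return out


def two_deme_branch_jsfs(
    n1: int, n2: int, N1: float, N2: float, NA: float, T_div: float,
    mig: float, mig_lo: float, mig_hi: float, n_sims: int, rng_seed: int,
) -> np.ndarray:
    """Expected unfolded branch-length joint SFS on the (n1+1, n2+1) grid.

    Migration is clipped at 4*min(N1,N2)*m = 50: beyond that the spectrum
    is saturated at its strong-migration limit (differences are far below
    simulation noise) while the event count -- and hence runtime -- keeps
    growing linearly in m.
    """
    if mig > 0.0:
        mig = min(float(mig), 12.5 / min(float(N1), float(N2)))
    return _two_deme_gillespie(
        int(n1), int(n2), float(N1), float(N2), float(NA), float(T_div),
        float(mig), float(mig_lo), float(mig_hi), int(n_sims),
        int(rng_seed) % (2**31 - 1),
    )


# ---------------------------------------------------------------------------
# public entry point


def expected_sfs(
    model, params: dict, like, n_sims: int = 10_000, rng_seed: int = 0,
    floor: float | None = None,
) -> np.ndarray:
    """Expected folded spectrum proportions conditioned on polymorphism.

    ``like`` supplies the target shape and mask (an observed
    :class:`~demearc.sfstools.FoldedSFS` or
    :class:`~demearc.sfstools.JointFoldedSFS`). The monomorphic class is
    excluded and the remaining mass renormalized (the no-invariant-sites
    likelihood regime); unmasked entries are floored at ``floor`` (default
    ``0.1 / n_sims``) before normalization so the composite likelihood stays
    finite.
    """
    spec = get_model(model)
    p = validate_params(spec, params)
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    if floor is None:
        floor = 0.1 / n_sims

    if spec.n_demes == 1:
        if not isinstance(like, FoldedSFS):
            raise ValueError("single-deme model needs a 1-D folded spectrum")
        n = like.n_lineages
        starts, sizes = single_deme_epochs(spec, p)
        unfolded = single_deme_branch_sfs(starts, sizes, n, n_sims, rng_seed)
        raw = fold_1d(unfolded)
        mask = like.mask
    else:
        if not isinstance(like, JointFoldedSFS):
            raise ValueError("two-deme model needs a joint folded spectrum")
        n1, n2 = like.n1_lineages, like.n2_lineages
        N1, N2, NA, tdiv, mig, lo, hi = two_deme_layout(spec, p)
        unfolded = two_deme_branch_jsfs(
            n1, n2, N1, N2, NA, tdiv, mig, lo, hi, n_sims, rng_seed)
        raw, _ = fold_2d(unfolded)
        mask = like.mask

    total = raw[~mask].sum()
    if total <= 0:
        raise ValueError(
            "expected spectrum carries no polymorphic mass at these "
            "parameters; increase the mutation/size scaling")
    props = np.zeros_like(raw)
    props[~mask] = np.maximum(raw[~mask] / total, floor)
    props[~mask] /= props[~mask].sum()
    return props
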