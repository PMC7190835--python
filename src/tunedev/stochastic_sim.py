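"""Stochastic simulation of the TES reaction network.

Two engines over the same :class:`~tunedev.kinetic_model.ReactionNetwork`:
an exact Gillespie direct-method SSA (the reference) and an adaptive
tau-leap integrator (the workhorse for ensembles), plus ensemble
generation that mirrors flow-cytometry population readouts: n independent
cells, each started at the (integer-rounded) deterministic steady state,
simulated for a fixed duration, contributing one terminal statistic
(protein copies or instantaneous protein production rate).

Both engines are deterministic given a seed; ensembles derive one child
seed per run from the master seed through ``numpy.random.SeedSequence``
spawning, so they are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from tunedev.kinetic_model import (
    ReactionNetwork,
    TESParameters,
    build_tes_network,
    steady_state,
)

__all__ = [
    "Trajectory",
    "Ensemble",
    "TauLeapError",
    "simulate_ssa",
    "simulate_tauleap",
    "run_ensemble",
    "ensemble_intersection",
]


class TauLeapError(RuntimeError):
    """Tau-leap step-size underflow."""


@dataclass(frozen=True)
class Trajectory:
    """A single stochastic path: integer copy numbers at recorded times."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species) integers
    seed: int
    method: Literal["exact-ssa", "tau-leap"]
    species: tuple[str, ...]
    absorbed: bool = False

    def __post_init__(self) -> None:
        if np.any(self.states < 0):
            raise ValueError("trajectory states must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class Ensemble:
    """Per-cell terminal statistics for one (input, tuner) condition."""

    terminal_values: np.ndarray
    condition: tuple[float, float]  # (u_in, u_tun)
    statistic: str
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.terminal_values < 0):
            raise ValueError("ensemble statistics must be non-negative")

    @property
    def n(self) -> int:
        return self.terminal_values.size


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _propensities(rates, orders, x, out):
    n_r, n_sp = orders.shape
    for j in range(n_r):
        a = rates[j]
        for i in range(n_sp):
            o = orders[j, i]
            for r in range(o):
                a *= max(x[i] - r, 0.0) / (r + 1.0)
        out[j] = a
    return out


@njit(cache=True)
def _ssa_core(stoich, rates, orders, x0, duration, seed, record_events):
    """Gillespie direct method.

    Records the initial state and (optionally) every jump; always records
    the terminal state.  Returns (times, states, n_recorded, absorbed).
    """
    np.random.seed(seed)
    n_sp, n_r = stoich.shape
    cap = 4096
    times = np.empty(cap)
    states = np.empty((cap, n_sp), dtype=np.int64)
    x = x0.copy()
    t = 0.0
    k = 0
    times[k] = t
    states[k] = x
    k += 1
    a = np.empty(n_r)
    absorbed = False
    while True:
        _propensities(rates, orders, x, a)
        a0 = 0.0
        for j in range(n_r):
            a0 += a[j]
        if a0 <= 0.0:
            absorbed = True
            break
        t += np.random.exponential(1.0 / a0)
        if t >= duration:
            t = duration
            break
        r = np.random.random() * a0
        acc = 0.0
        mu = n_r - 1
        for j in range(n_r):
            acc += a[j]
            if r < acc:
                mu = j
                break
        for i in range(n_sp):
            x[i] += stoich[i, mu]
        if record_events:
            if k >= cap:
                cap *= 2
                new_t = np.empty(cap)
                new_s = np.empty((cap, n_sp), dtype=np.int64)
                new_t[:k] = times[:k]
                new_s[:k] = states[:k]
                times = new_t
                states = new_s
            times[k] = t
            states[k] = x
            k += 1
    # terminal record (skip duplicate time when an event landed exactly there)
    if t > times[k - 1]:
        if k >= cap:
            cap += 1
            new_t = np.empty(cap)
            new_s = np.empty((cap, n_sp), dtype=np.int64)
            new_t[:k] = times[:k]
            new_s[:k] = states[:k]
            times = new_t
            states = new_s
        times[k] = t
        states[k] = x
        k += 1
    return times[:k], states[:k], absorbed


@njit(cache=True)
def _tauleap_core(stoich, rates, orders, x0, duration, n_intervals, epsilon, seed):
    """Adaptive tau-leap with Poisson updates, recorded at interval boundaries.

    The leap is bounded by the recording interval and by the
    bounded-relative-change criterion (expected relative change of every
    reactant species <= epsilon); candidate leaps whose Poisson draws would
    drive a species negative are halved and redrawn.  Returns
    (states, status) with status 0 = ok, 1 = step underflow.
    """
    np.random.seed(seed)
    n_sp, n_r = stoich.shape
    dt_rec = duration / n_intervals
    rec = np.empty((n_intervals + 1, n_sp), dtype=np.int64)
    x = x0.astype(np.float64)
    rec[0] = x0
    a = np.empty(n_r)
    for interval in range(n_intervals):
        t_local = 0.0
        while t_local < dt_rec - 1e-12:
            _propensities(rates, orders, x, a)
            a0 = 0.0
            for j in range(n_r):
                a0 += a[j]
            if a0 <= 0.0:
                break  # absorbed: state frozen for the rest of the interval
            # bounded relative change (mean and variance terms):
            # tau <= eps*x_i/|mu_i|  and  tau <= (eps*x_i)^2/sigma2_i
            remainder = dt_rec - t_local
            tau = remainder
            for i in range(n_sp):
                mu = 0.0
                sig2 = 0.0
                for j in range(n_r):
                    mu += stoich[i, j] * a[j]
                    sig2 += stoich[i, j] * stoich[i, j] * a[j]
                bound = epsilon * max(x[i], 1.0)
                if mu != 0.0 and bound / abs(mu) < tau:
                    tau = bound / abs(mu)
                if sig2 > 0.0 and bound * bound / sig2 < tau:
                    tau = bound * bound / sig2
            if tau < 10.0 / a0 and tau < remainder:
                # leaping is no cheaper than exact simulation here: take a
                # batch of exact SSA steps instead (standard hybrid rule)
                for _ in range(20):
                    _propensities(rates, orders, x, a)
                    a0 = 0.0
                    for j in range(n_r):
                        a0 += a[j]
                    if a0 <= 0.0:
                        break
                    dt_step = np.random.exponential(1.0 / a0)
                    if t_local + dt_step >= dt_rec:
                        t_local = dt_rec
                        break
                    t_local += dt_step
                    r = np.random.random() * a0
                    acc = 0.0
                    mu_r = n_r - 1
                    for j in range(n_r):
                        acc += a[j]
                        if r < acc:
                            mu_r = j
                            break
                    for i in range(n_sp):
                        x[i] += stoich[i, mu_r]
                continue
            accepted = False
            while not accepted:
                # a sub-1e-6 step is only a failure when the criterion or
                # halving forced it, not when it is the last sliver of the
                # recording interval
                if tau < 1e-6 and tau < remainder:
                    return rec, 1
                xn = x.copy()
                ok = True
                for j in range(n_r):
                    if a[j] <= 0.0:
                        continue
                    kj = np.random.poisson(a[j] * tau)
                    if kj == 0:
                        continue
                    for i in range(n_sp):
                        xn[i] += stoich[i, j] * kj
                for i in range(n_sp):
                    if xn[i] < 0:
                        ok = False
                        break
                if ok:
                    x = xn
                    t_local += tau
                    accepted = True
                else:
                    tau *= 0.5
        rec[interval + 1] = x.astype(np.int64)
    return rec, 0


@njit(cache=True)
def _ssa_terminal(stoich, rates, orders, x0, duration, seed):
    """Terminal state of an exact-SSA run (no path recording)."""
    np.random.seed(seed)
    n_sp, n_r = stoich.shape
    x = x0.copy()
    t = 0.0
    a = np.empty(n_r)
    while True:
        _propensities(rates, orders, x, a)
        a0 = 0.0
        for j in range(n_r):
            a0 += a[j]
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t >= duration:
            break
        r = np.random.random() * a0
        acc = 0.0
        mu = n_r - 1
        for j in range(n_r):
            acc += a[j]
            if r < acc:
                mu = j
                break
        for i in range(n_sp):
            x[i] += stoich[i, mu]
    return x


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _as_int_state(network: ReactionNetwork, initial) -> np.ndarray:
    x0 = np.asarray(initial)
    if x0.shape != (len(network.species),):
        raise ValueError(f"initial state must have {len(network.species)} entries")
    if np.any(x0 < 0) or not np.allclose(x0, np.round(x0)):
        raise ValueError("initial state must be non-negative integers")
    return x0.astype(np.int64)


def simulate_ssa(
    network: ReactionNetwork,
    initial,
    duration: float,
    seed: int,
    record_events: bool = True,
) -> Trajectory:
    """Exact Gillespie direct-method simulation of ``network``.

    Event waiting times are exponential in the total propensity and each
    firing applies one stoichiometry column exactly.  If all propensities
    vanish the path is flagged ``absorbed`` and ends early.
    """
    x0 = _as_int_state(network, initial)
    times, states, absorbed = _ssa_core(
        network.stoichiometry, network.rate_constants, network.reactant_orders,
        x0, float(duration), int(seed) & 0x7FFFFFFF, record_events,
    )
    return Trajectory(
        times=times, states=states, seed=int(seed), method="exact-ssa",
        species=network.species, absorbed=bool(absorbed),
    )


def simulate_tauleap(
    network: ReactionNetwork,
    initial,
    duration: float = 100.0,
    n_intervals: int = 100,
    seed: int = 0,
    epsilon: float = 0.03,
) -> Trajectory:
    """Adaptive tau-leap simulation recorded at ``n_intervals + 1`` boundaries.

    Within each recording interval the leap size satisfies the
    bounded-relative-propensity criterion (default ``epsilon = 0.03``);
    negative excursions are resolved by step halving, never clipped.
    Raises :class:`TauLeapError` if the step underflows below 1e-6 min.
    """
    x0 = _as_int_state(network, initial)
    rec, status = _tauleap_core(
        network.stoichiometry, network.rate_constants, network.reactant_orders,
        x0, float(duration), int(n_intervals), float(epsilon),
        int(seed) & 0x7FFFFFFF,
    )
    if status != 0:
        raise TauLeapError("tau-leap step size underflowed below 1e-6 min")
    times = np.linspace(0.0, duration, n_intervals + 1)
    # recording grid starts at 0; Trajectory demands strictly increasing times
    return Trajectory(
        times=times, states=rec, seed=int(seed), method="tau-leap",
        species=network.species,
    )


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_ensemble(
    params: TESParameters,
    n: int = 4000,
    seed: int = 0,
    statistic: Literal["protein", "production_rate"] = "production_rate",
    duration: float = 100.0,
    n_intervals: int = 100,
    epsilon: float = 0.03,
    method: Literal["tau-leap", "exact-ssa"] = "tau-leap",
) -> Ensemble:
    """Simulate ``n`` independent cells and collect a terminal statistic.

    Each cell starts at the deterministic steady state rounded
    half-to-even to integers, runs for ``duration`` minutes, and
    contributes either its terminal protein copy number or its terminal
    instantaneous production rate ``k_leak*m + k_act*c``.  Per-cell seeds
    are spawned from ``seed``.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    network = build_tes_network(params)
    x0 = np.rint(steady_state(params).as_array()).astype(np.int64)  # round-half-even
    seeds = child_seeds(seed, n)
    values = np.empty(n)
    S, k, O = network.stoichiometry, network.rate_constants, network.reactant_orders
    for i in range(n):
        try:
            if method == "tau-leap":
                rec, status = _tauleap_core(S, k, O, x0, float(duration),
                                            int(n_intervals), float(epsilon), seeds[i])
                if status != 0:
                    raise TauLeapError("tau-leap step size underflowed below 1e-6 min")
                x = rec[-1]
            else:
                x = _ssa_terminal(S, k, O, x0, float(duration), seeds[i])
        except TauLeapError as err:
            raise TauLeapError(f"run {i} failed: {err}") from err
        if statistic == "protein":
            values[i] = x[3]
        else:
            values[i] = params.k_leak * x[0] + params.k_act * x[2]
    return Ensemble(
        terminal_values=values,
        condition=(params.u_in, params.u_tun),
        statistic=statistic,
        seed=int(seed),
    )


def ensemble_intersection(a: Ensemble, b: Ensemble, n_bins: int = 256) -> float:
    """Fractional overlap of two ensembles' terminal-statistic distributions.

    Histograms both ensembles on shared bin edges and delegates to
    :func:`tunedev.cytometry_stats.intersection_fraction`.
    """
    from tunedev.cytometry_stats import histogram_pair, intersection_fraction

    if a.n == 0 or b.n == 0:
        raise ValueError("both ensembles must be non-empty")
    return intersection_fraction(histogram_pair(a.terminal_values, b.terminal_values, n_bins))
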