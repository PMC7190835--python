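"""Deterministic models of the tunable expression system (TES).

A TES couples two transcriptional inputs to one protein output: a main
input promoter transcribes an mRNA whose ribosome binding site is occluded
by a toehold-switch (THS) hairpin, and a tuner promoter transcribes a small
RNA (sRNA) complementary to the THS toehold.  Binding of the sRNA opens the
hairpin by branch migration and raises the translation initiation rate of
the mRNA, so the tuner input sets the translational gain of the device
while the main input sets its transcriptional drive.

The mass-action species are

    m : free (closed) THS mRNA        [copies/cell]
    s : free tuner sRNA               [copies/cell]
    c : mRNA-sRNA complex (open)      [copies/cell]
    p : output protein                [copies/cell]

with reactions

    0 -> m          at u_in                       (input transcription)
    0 -> s          at booster_factor * u_tun     (tuner transcription)
    m + s -> c      at k_on                       (toehold hybridization)
    c -> m + s      at k_off                      (dissociation; 0 = irreversible)
    m -> m + p      at k_leak                     (leaky translation, closed switch)
    c -> c + p      at k_act                      (activated translation, open switch)
    x -> 0          at delta_x + phi  for x in (m, s, c, p)

This module provides the deterministic (ODE/DDE) engines, steady-state
solvers, response surfaces, NOT/NOR gate compositions, and a
ribosome-allocation coupling that captures retroactivity-like burden
effects.  Stochastic engines over the same :class:`ReactionNetwork` live in
:mod:`tunedev.stochastic_sim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "TESParameters",
    "GateParameters",
    "HostParameters",
    "DelayTimes",
    "SteadyStateState",
    "ReactionNetwork",
    "SteadyStateError",
    "IntegrationError",
    "UndefinedRatioError",
    "NOMINAL",
    "LOW_COPY",
    "CHARACTERIZATION",
    "RPU_TO_RNAP",
    "rpu_to_rnap",
    "rnap_to_rpu",
    "build_tes_network",
    "steady_state",
    "simulate_ode_timecourse",
    "simulate_dde_timecourse",
    "response_surface",
    "ths_tuner_ratio",
    "fold_change_profile",
    "not_gate_response",
    "nor_gate_response",
    "coupled_steady_state",
]

SPECIES = ("m", "s", "c", "p")

#: Default bridge between relative promoter units (RPU) and RNAP initiation
#: flux.  The conversion is not a physical constant; 79 RNAP/min per RPU
#: places the strongest experimental tuner activity (2.6 RPU) near the top
#: of the model tuner grid (190 RNAP/min) and is exposed as configuration.
RPU_TO_RNAP = 79.0


def rpu_to_rnap(rpu: float, factor: float = RPU_TO_RNAP) -> float:
    """Convert a promoter activity in RPU to RNAP initiations per minute."""
    return rpu * factor


def rnap_to_rpu(rnap: float, factor: float = RPU_TO_RNAP) -> float:
    """Convert an RNAP/min transcription rate to RPU."""
    return rnap / factor


class SteadyStateError(RuntimeError):
    """Steady-state solve failed; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


class IntegrationError(RuntimeError):
    """Time-course integration failed; carries the breakdown time."""

    def __init__(self, message: str, t_break: float):
        super().__init__(f"{message} (breakdown at t = {t_break:.6g} min)")
        self.t_break = t_break


class UndefinedRatioError(ZeroDivisionError):
    """THS:sRNA ratio requested with zero total sRNA."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TESParameters:
    """Kinetic rates and promoter activities of the TES.

    All first-order rates are per minute; ``k_on`` is per molecule per
    minute; ``u_in`` and ``u_tun`` are transcription initiation fluxes in
    RNAP/min (transcripts per minute per cell).  Defaults are biologically
    realistic nominal values for an *E. coli* host: a 5-min mRNA half-life,
    a 1-min sRNA half-life (unpaired trans-acting sRNAs turn over quickly),
    a stable reporter protein removed only by dilution at a 30-min doubling
    time, and a 100-fold span between leaky and activated translation
    initiation.  The default ``k_on`` places tuner binding in the weak
    (sub-stoichiometric-capture) regime where the device's response to the
    tuner stays graded across the full tuner activity range; see
    ``LOW_COPY`` for the strong-binding regime.  ``booster_factor``
    multiplies tuner transcription and models a high-copy sRNA booster
    plasmid (about 5x for a pColE1 booster against a p15A device
    backbone); the plain device has no booster, so it defaults to 1.
    """

    u_in: float = 1.5
    u_tun: float = 38.0
    k_on: float = 1e-4
    k_off: float = 0.0
    k_leak: float = 0.02
    k_act: float = 2.0
    delta_m: float = 0.1386
    delta_s: float = 0.6931
    delta_c: float = 0.1386
    delta_p: float = 0.0
    phi: float = 0.0231
    booster_factor: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"TESParameters.{f.name} must be finite and >= 0, got {v!r}")
        for d in ("delta_m", "delta_s", "delta_p"):
            if getattr(self, d) + self.phi <= 0:
                raise ValueError(f"TESParameters.{d} + phi must be positive")
        if self.k_act < self.k_leak:
            raise ValueError(
                f"TESParameters.k_act ({self.k_act}) must be >= k_leak ({self.k_leak}): "
                "the opened switch translates at least as fast as the closed one"
            )
        if self.booster_factor < 1:
            raise ValueError(f"TESParameters.booster_factor must be >= 1, got {self.booster_factor}")

    def with_inputs(self, u_in: float | None = None, u_tun: float | None = None) -> "TESParameters":
        """Copy with replaced promoter activities."""
        kw = {}
        if u_in is not None:
            kw["u_in"] = u_in
        if u_tun is not None:
            kw["u_tun"] = u_tun
        return replace(self, **kw) if kw else self


#: Nominal parameter set used throughout the package: weak tuner binding,
#: fast sRNA turnover.  In this regime sequestration stays sub-saturating
#: over the whole tuner activity range, so the deterministic response to the
#: tuner is graded and fold change shrinks monotonically as the tuner rises.
NOMINAL = TESParameters()

#: Strong-binding, low-copy-number operating point.  Tuner capture is fast
#: relative to RNA turnover and molecule counts are small (a few transcripts
#: per cell), so output is dominated by translation from the bound complex
#: and cell-to-cell variability is large.  This is the regime used for
#: single-cell (stochastic) studies of tuner-mediated noise reduction.
LOW_COPY = replace(NOMINAL, k_on=0.05, delta_s=0.2310)

#: Characterization operating point used by the synthetic-data generator:
#: intermediate binding strength placing the half-saturation of sRNA capture
#: in the middle of the standard input grid, so the per-tuner response
#: curves saturate within the measured range and their Hill transition
#: points are identifiable from grid data.
CHARACTERIZATION = replace(NOMINAL, k_on=0.002, delta_s=0.2310)


@dataclass(frozen=True)
class GateParameters:
    """Repressor/output-promoter parameters for NOT and NOR gates.

    The TES drives a repressor (e.g. PhlF) whose steady-state level
    represses a constitutive output promoter through a Hill function.
    ``kappa_rt`` adds transcriptional read-through flux from an upstream
    tuner unit onto the repressor gene (0 = fully insulated).
    """

    p_out_max: float = 4.0
    p_out_min: float = 0.02
    K_R: float = 150.0
    n_R: float = 2.0
    kappa_rt: float = 0.0

    def __post_init__(self) -> None:
        if not self.p_out_max > self.p_out_min >= 0:
            raise ValueError(
                f"GateParameters requires p_out_max > p_out_min >= 0, got "
                f"({self.p_out_max}, {self.p_out_min})"
            )
        if self.K_R <= 0:
            raise ValueError(f"GateParameters.K_R must be > 0, got {self.K_R}")
        if self.n_R <= 0:
            raise ValueError(f"GateParameters.n_R must be > 0, got {self.n_R}")
        if self.kappa_rt < 0:
            raise ValueError(f"GateParameters.kappa_rt must be >= 0, got {self.kappa_rt}")


@dataclass(frozen=True)
class HostParameters:
    """Lumped host ribosome pool for the resource-coupled model.

    ``R_total`` ribosomes are shared between endogenous demand
    (``host_demand``, in sequestered-ribosome equivalents at full
    availability) and the synthetic construct; translation saturates in
    free ribosomes with half-saturation ``K_rib``.  ``w_occupancy`` is the
    mean time (min) a ribosome is bound per protein synthesized, converting
    synthesis flux to sequestered ribosomes.
    """

    R_total: float = 20000.0
    host_demand: float = 15000.0
    K_rib: float = 1000.0
    w_occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.R_total <= 0:
            raise ValueError(f"HostParameters.R_total must be > 0, got {self.R_total}")
        if self.host_demand < 0:
            raise ValueError(f"HostParameters.host_demand must be >= 0, got {self.host_demand}")
        if self.K_rib <= 0:
            raise ValueError(f"HostParameters.K_rib must be > 0, got {self.K_rib}")
        if self.w_occupancy < 0:
            raise ValueError(f"HostParameters.w_occupancy must be >= 0, got {self.w_occupancy}")


@dataclass(frozen=True)
class DelayTimes:
    """Per-stage delays (minutes) for the delay-differential variant.

    ``transcription`` delays the appearance of new transcripts after
    initiation; ``translation`` delays protein appearance (elongation plus
    fluorophore maturation) after the ribosome loads.
    """

    transcription: float = 0.0
    translation: float = 0.0

    def __post_init__(self) -> None:
        if self.transcription < 0 or self.translation < 0:
            raise ValueError("DelayTimes must be >= 0")


@dataclass(frozen=True)
class SteadyStateState:
    """A (steady) state of the TES with its instantaneous synthesis rate."""

    m: float
    s: float
    c: float
    p: float
    production_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.s, self.c, self.p], dtype=float)

    @staticmethod
    def from_array(x: Sequence[float], params: "TESParameters") -> "SteadyStateState":
        m, s, c, p = (float(v) for v in x)
        return SteadyStateState(m, s, c, p, params.k_leak * m + params.k_act * c)


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionNetwork:
    """Mass-action reaction system shared by the ODE and stochastic engines.

    ``stoichiometry`` has one column per reaction (rows follow ``species``);
    ``rate_constants[j]`` and ``reactant_orders[j]`` define reaction *j*'s
    mass-action propensity  k_j * prod_i x_i^(order_ji)  (with falling
    factorials in the stochastic engines).
    """

    species: tuple[str, ...]
    stoichiometry: np.ndarray
    rate_constants: np.ndarray
    reactant_orders: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.stoichiometry)
        k = np.asarray(self.rate_constants, dtype=float)
        O = np.asarray(self.reactant_orders)
        if S.shape != (len(self.species), k.size):
            raise ValueError("stoichiometry must be (n_species, n_reactions)")
        if O.shape != (k.size, len(self.species)):
            raise ValueError("reactant_orders must be (n_reactions, n_species)")
        if np.any(k < 0):
            raise ValueError("all mass-action rate constants must be >= 0")
        object.__setattr__(self, "stoichiometry", S.astype(np.int64))
        object.__setattr__(self, "rate_constants", k)
        object.__setattr__(self, "reactant_orders", O.astype(np.int64))

    @property
    def n_reactions(self) -> int:
        return self.rate_constants.size

    def propensities(self, state: np.ndarray) -> np.ndarray:
        """Stochastic propensities at an integer state (falling factorials)."""
        x = np.asarray(state, dtype=float)
        a = self.rate_constants.copy()
        for j in range(self.n_reactions):
            for i in np.nonzero(self.reactant_orders[j])[0]:
                order = self.reactant_orders[j, i]
                for r in range(order):
                    a[j] *= max(x[i] - r, 0.0) / (r + 1)
        return a

    def deterministic_rates(self, state: np.ndarray) -> np.ndarray:
        """Concentration-style mass-action rates (plain powers)."""
        x = np.asarray(state, dtype=float)
        return self.rate_constants * np.prod(
            np.power(np.maximum(x, 0.0)[None, :], self.reactant_orders), axis=1
        )

    def ode_rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        return self.stoichiometry @ self.deterministic_rates(state)


def build_tes_network(params: TESParameters) -> ReactionNetwork:
    """Assemble the 10-reaction, 4-species TES mass-action network.

    Species order is fixed as ``(m, s, c, p)``; reactions follow the order
    documented in the module docstring.
    """
    i = {sp: idx for idx, sp in enumerate(SPECIES)}
    n_sp = len(SPECIES)
    cols: list[np.ndarray] = []
    rates: list[float] = []
    orders: list[np.ndarray] = []

    def rxn(rate: float, reactants: dict, products: dict) -> None:
        col = np.zeros(n_sp, dtype=np.int64)
        order = np.zeros(n_sp, dtype=np.int64)
        for sp, nu in reactants.items():
            col[i[sp]] -= nu
            order[i[sp]] += nu
        for sp, nu in products.items():
            col[i[sp]] += nu
        cols.append(col)
        rates.append(rate)
        orders.append(order)

    rxn(params.u_in, {}, {"m": 1})
    rxn(params.booster_factor * params.u_tun, {}, {"s": 1})
    rxn(params.k_on, {"m": 1, "s": 1}, {"c": 1})
    rxn(params.k_off, {"c": 1}, {"m": 1, "s": 1})
    rxn(params.k_leak, {"m": 1}, {"m": 1, "p": 1})
    rxn(params.k_act, {"c": 1}, {"c": 1, "p": 1})
    rxn(params.delta_m + params.phi, {"m": 1}, {})
    rxn(params.delta_s + params.phi, {"s": 1}, {})
    rxn(params.delta_c + params.phi, {"c": 1}, {})
    rxn(params.delta_p + params.phi, {"p": 1}, {})

    return ReactionNetwork(
        species=SPECIES,
        stoichiometry=np.column_stack(cols),
        rate_constants=np.array(rates),
        reactant_orders=np.vstack(orders),
    )


def tes_rhs(params: TESParameters, state: np.ndarray) -> np.ndarray:
    """Hand-written TES ODE right-hand side (used by solvers; fast path)."""
    m, s, c, p = state
    bind = params.k_on * m * s - params.k_off * c
    dm = params.u_in - (params.delta_m + params.phi) * m - bind
    ds = params.booster_factor * params.u_tun - (params.delta_s + params.phi) * s - bind
    dc = bind - (params.delta_c + params.phi) * c
    dp = params.k_leak * m + params.k_act * c - (params.delta_p + params.phi) * p
    return np.array([dm, ds, dc, dp])


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def steady_state(
    params: TESParameters,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> SteadyStateState:
    """Exact steady state of the TES ODEs.

    The four balances reduce to a single bracketed scalar equation in free
    mRNA m (summing the m and s balances eliminates the bilinear binding
    term), which is solved to machine precision with Brent's method; the
    other species follow in closed form.  A long-time integration fallback
    covers any residual above ``tol`` (in copies/min).
    """
    gm = params.delta_m + params.phi
    gs = params.delta_s + params.phi
    gc = params.delta_c + params.phi
    gp = params.delta_p + params.phi
    u_s = params.booster_factor * params.u_tun
    if params.k_on > 0 and params.k_off + gc == 0 and params.u_in > 0 and u_s > 0:
        raise SteadyStateError("complex accumulates without bound (k_off + delta_c + phi = 0)", np.inf)

    # effective irreversible capture rate: the k_off back-flux returns a
    # fraction k_off/(k_off+gc) of bound pairs, so net capture is scaled
    k_eff = params.k_on * gc / (params.k_off + gc) if (params.k_off + gc) > 0 else 0.0

    def s_of_m(m: float) -> float:
        # from (m-balance) - (s-balance): gm*m - u_in = gs*s - u_s
        return (gm * m - params.u_in + u_s) / gs

    def g(m: float) -> float:
        return params.u_in - gm * m - k_eff * m * s_of_m(m)

    m_max = params.u_in / gm
    m_min = max(0.0, (params.u_in - u_s) / gm)
    if k_eff == 0.0 or params.u_in == 0.0 or u_s == 0.0:
        m = m_max
    else:
        lo, hi = m_min, m_max
        if g(lo) < 0 or g(hi) > 0:  # bracket failed; fall back to integration
            return _steady_state_by_integration(params, tol)
        m = brentq(g, lo, hi, xtol=1e-15, maxiter=max_iter)
        for _ in range(4):  # Newton polish to machine-level residual
            dg = -gm - k_eff * (s_of_m(m) + m * gm / gs)
            step = g(m) / dg
            if not np.isfinite(step):
                break
            m = min(max(m - step, lo), hi)
    s = max(s_of_m(m), 0.0)
    c = params.k_on * m * s / (params.k_off + gc) if (params.k_off + gc) > 0 else 0.0
    prod = params.k_leak * m + params.k_act * c
    p = prod / gp
    state = SteadyStateState(m, s, c, p, prod)
    resid = float(np.max(np.abs(tes_rhs(params, state.as_array()))))
    if resid > tol:
        return _steady_state_by_integration(params, tol, start=state.as_array())
    return state


def _steady_state_by_integration(
    params: TESParameters, tol: float, start: np.ndarray | None = None
) -> SteadyStateState:
    rates = [params.delta_m, params.delta_s, params.delta_p]
    g_min = min(r + params.phi for r in rates)
    t_end = max(1e4, 40.0 / g_min)
    x0 = np.zeros(4) if start is None else start
    sol = solve_ivp(
        lambda t, x: tes_rhs(params, x), (0.0, t_end), x0,
        method="LSODA", rtol=1e-12, atol=1e-10,
    )
    x = np.maximum(sol.y[:, -1], 0.0)
    resid = float(np.max(np.abs(tes_rhs(params, x))))
    if not sol.success or resid > tol:
        raise SteadyStateError("steady-state solve did not converge", resid)
    return SteadyStateState.from_array(x, params)


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------


def simulate_ode_timecourse(
    params: TESParameters,
    initial: SteadyStateState | Sequence[float],
    duration: float,
    n_points: int = 101,
) -> pd.DataFrame:
    """Integrate the TES ODEs from ``initial`` for ``duration`` minutes.

    Returns a tidy frame with columns ``time, m, s, c, p, production_rate``
    on ``n_points`` evenly spaced output times (first row = initial state).
    Uses a stiff-capable integrator (LSODA).
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    x0 = initial.as_array() if isinstance(initial, SteadyStateState) else np.asarray(initial, float)
    if x0.shape != (4,) or np.any(x0 < 0):
        raise ValueError("initial state must be 4 non-negative values (m, s, c, p)")
    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(
        lambda t, x: tes_rhs(params, x), (0.0, duration), x0,
        method="LSODA", t_eval=t_eval, rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError("ODE integration failed", float(sol.t[-1]) if sol.t.size else 0.0)
    out = pd.DataFrame(sol.y.T, columns=list(SPECIES))
    out.insert(0, "time", sol.t)
    out["production_rate"] = params.k_leak * out["m"] + params.k_act * out["c"]
    return out


def simulate_dde_timecourse(
    params: TESParameters,
    delays: DelayTimes,
    initial: SteadyStateState | Sequence[float],
    duration: float,
    n_points: int = 101,
    dt: float | None = None,
) -> pd.DataFrame:
    """Delay-differential variant: maturation lags on transcription/translation.

    New transcripts appear ``delays.transcription`` minutes after initiation
    and new protein ``delays.translation`` minutes after ribosome loading;
    the history before t=0 is the initial state held constant.  Solved with
    fixed-step RK4 and linear interpolation into the stored history; with
    both delays zero the scheme reduces to a plain RK4 ODE solve.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    x0 = initial.as_array() if isinstance(initial, SteadyStateState) else np.asarray(initial, float)
    if x0.shape != (4,) or np.any(x0 < 0):
        raise ValueError("initial state must be 4 non-negative values (m, s, c, p)")
    tau_tx, tau_tl = delays.transcription, delays.translation
    pos = [t for t in (tau_tx, tau_tl) if t > 0]
    if dt is None:
        dt = min([0.02] + [t / 20 for t in pos])
    n_steps = int(np.ceil(duration / dt))
    dt = duration / n_steps

    ts = np.arange(n_steps + 1) * dt
    X = np.empty((n_steps + 1, 4))
    X[0] = x0

    gm = params.delta_m + params.phi
    gs = params.delta_s + params.phi
    gc = params.delta_c + params.phi
    gp = params.delta_p + params.phi
    u_s = params.booster_factor * params.u_tun

    def hist(t: float, upto: int) -> np.ndarray:
        """Linear interpolation of the stored solution at time t <= ts[upto]."""
        if t <= 0.0:
            return x0
        idx = min(int(t / dt), upto - 1)
        w = (t - ts[idx]) / dt
        return (1 - w) * X[idx] + w * X[idx + 1]

    def rhs(t: float, x: np.ndarray, upto: int) -> np.ndarray:
        m, s, c, p = x
        # constant-input transcription: the delayed flux equals the flux
        xd_tl = x if tau_tl == 0.0 else hist(t - tau_tl, upto)
        bind = params.k_on * m * s - params.k_off * c
        dm = params.u_in - gm * m - bind
        ds = u_s - gs * s - bind
        dc = bind - gc * c
        dp = params.k_leak * xd_tl[0] + params.k_act * xd_tl[2] - gp * p
        return np.array([dm, ds, dc, dp])

    for k in range(n_steps):
        t, x = ts[k], X[k]
        k1 = rhs(t, x, k)
        k2 = rhs(t + dt / 2, x + dt / 2 * k1, k)
        k3 = rhs(t + dt / 2, x + dt / 2 * k2, k)
        k4 = rhs(t + dt, x + dt * k3, k)
        X[k + 1] = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(X[k + 1])):
            raise IntegrationError("DDE integration diverged", float(ts[k + 1]))

    keep = np.linspace(0, n_steps, n_points).round().astype(int)
    out = pd.DataFrame(X[keep], columns=list(SPECIES))
    out.insert(0, "time", ts[keep])
    out["production_rate"] = params.k_leak * out["m"] + params.k_act * out["c"]
    return out


# ---------------------------------------------------------------------------
# Response surfaces and derived diagnostics
# ---------------------------------------------------------------------------

OutputStatistic = Literal["protein", "production_rate"]


def _output(state: SteadyStateState, statistic: OutputStatistic) -> float:
    return state.p if statistic == "protein" else state.production_rate


def _check_grid(grid: Sequence[float], name: str) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.any(g < 0):
        raise ValueError(f"{name} must be non-negative")
    if g.size > 1 and np.any(np.diff(g) <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    return g


def response_surface(
    params: TESParameters,
    input_grid: Sequence[float],
    tuner_grid: Sequence[float],
    statistic: OutputStatistic = "protein",
) -> pd.DataFrame:
    """Steady-state output over an input x tuner grid (RNAP/min units).

    Returns a tidy frame with columns ``tuner_activity, input_activity,
    output`` — one Hill-shaped response curve per tuner level, shifting
    upward with tuner activity.
    """
    u_ins = _check_grid(input_grid, "input_grid")
    u_tuns = _check_grid(tuner_grid, "tuner_grid")
    rows = []
    for u_t in u_tuns:
        for u_i in u_ins:
            try:
                st = steady_state(params.with_inputs(u_in=u_i, u_tun=u_t))
            except SteadyStateError as err:
                raise SteadyStateError(
                    f"steady state failed at input={u_i}, tuner={u_t}", err.residual
                ) from err
            rows.append((u_t, u_i, _output(st, statistic)))
    return pd.DataFrame(rows, columns=["tuner_activity", "input_activity", "output"])


def ths_tuner_ratio(params: TESParameters, include_complex: bool = True) -> float:
    """Steady-state ratio of THS transcript to tuner sRNA.

    By default counts the bound complex in both pools, (m + c)/(s + c);
    ``include_complex=False`` gives the free-species ratio m/s.
    """
    st = steady_state(params)
    num, den = (st.m + st.c, st.s + st.c) if include_complex else (st.m, st.s)
    if den <= 0.0:
        raise UndefinedRatioError(
            "THS:sRNA ratio undefined: total steady-state sRNA is zero"
        )
    return num / den


def fold_change_profile(
    params: TESParameters,
    u_in_low: float,
    u_in_high: float,
    tuner_grid: Sequence[float],
    statistic: OutputStatistic = "protein",
) -> pd.DataFrame:
    """On/off output fold change across tuner levels.

    ``fold = output(u_in_high)/output(u_in_low)`` per tuner level; for the
    deterministic model with default rates this decreases (weakly) as the
    tuner activity rises, because high-input output saturates on the
    limited sRNA pool first.  A zero low-input output yields ``fold = NaN``
    with the raw pair still reported.
    """
    if not (u_in_high > u_in_low >= 0):
        raise ValueError("require u_in_high > u_in_low >= 0")
    u_tuns = _check_grid(tuner_grid, "tuner_grid")
    rows = []
    for u_t in u_tuns:
        lo = _output(steady_state(params.with_inputs(u_in=u_in_low, u_tun=u_t)), statistic)
        hi = _output(steady_state(params.with_inputs(u_in=u_in_high, u_tun=u_t)), statistic)
        fold = hi / lo if lo > 0 else np.nan
        rows.append((u_t, lo, hi, fold))
    return pd.DataFrame(rows, columns=["tuner_activity", "output_low", "output_high", "fold_change"])


# ---------------------------------------------------------------------------
# Gate compositions
# ---------------------------------------------------------------------------


def not_gate_response(
    params: TESParameters,
    gate: GateParameters,
    u_in: float | None = None,
    u_tun: float | None = None,
) -> float:
    """Output promoter activity of a TES-driven NOT gate.

    The TES protein output is read as repressor copies r (computed with
    effective input ``u_in + kappa_rt`` to model tuner-unit read-through),
    and the output promoter follows a repression Hill function
    ``p_min + (p_max - p_min) * K_R^n / (K_R^n + r^n)``.
    """
    p = params.with_inputs(u_in=u_in, u_tun=u_tun)
    p = replace(p, u_in=p.u_in + gate.kappa_rt)
    r = steady_state(p).p
    frac = gate.K_R**gate.n_R / (gate.K_R**gate.n_R + r**gate.n_R)
    return gate.p_out_min + (gate.p_out_max - gate.p_out_min) * frac


def nor_gate_response(
    params: TESParameters,
    gate: GateParameters,
    u_a: float,
    u_b: float,
    u_tun: float | None = None,
) -> float:
    """Output of a two-input tandem-promoter NOR gate.

    The two input promoters transcribe the same repressor unit, so their
    RNAP fluxes add; the gate is then the NOT gate at effective input
    ``u_a + u_b`` (symmetric in its inputs by construction).
    """
    if u_a < 0 or u_b < 0:
        raise ValueError("NOR inputs must be >= 0")
    return not_gate_response(params, gate, u_in=u_a + u_b, u_tun=u_tun)


# ---------------------------------------------------------------------------
# Ribosome-allocation coupling (retroactivity/burden)
# ---------------------------------------------------------------------------


def coupled_steady_state(
    params: TESParameters,
    host: HostParameters,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SteadyStateState:
    """Steady state with translation throttled by a shared ribosome pool.

    Translation rates are scaled by the availability factor
    ``f = R_free/(K_rib + R_free)``, where the free pool solves the
    self-consistent allocation balance

        R_free = R_total - f(R_free) * (host_demand + w * (k_leak*m + k_act*c))

    by damped fixed-point iteration (to ``tol``).  RNA species are
    unaffected (translation does not consume the transcript), so only the
    protein level and synthesis rate shrink; as ``R_total`` grows the
    result converges to the uncoupled steady state.
    """
    base = steady_state(params)
    demand_flux = host.w_occupancy * (params.k_leak * base.m + params.k_act * base.c)

    R_free = host.R_total
    resid = np.inf
    for _ in range(max_iter):
        f = R_free / (host.K_rib + R_free)
        target = host.R_total - f * (host.host_demand + demand_flux * f)
        # note: construct sequestration also scales with availability f
        target = max(target, 0.0)
        resid = abs(target - R_free)
        R_free = 0.5 * R_free + 0.5 * target
        if resid < tol:
            break
    else:
        raise SteadyStateError("ribosome-allocation fixed point did not converge", resid)

    f = R_free / (host.K_rib + R_free)
    prod = f * (params.k_leak * base.m + params.k_act * base.c)
    gp = params.delta_p + params.phi
    return SteadyStateState(base.m, base.s, base.c, prod / gp, prod)
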