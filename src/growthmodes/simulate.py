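"""Stochastic simulators for single-cell growth and division.

Every simulator in this module generates synthetic mother-machine style
data: sequences of per-cycle records (birth length, division length,
generation time, per-cycle rate, optional event times) and, via
:func:`sample_trajectory`, length-vs-time samples on a fixed grid
(default 4 min, matching the imaging frame rate the data emulate).

Common structure of the lineage simulators:

* division is perfectly symmetric — the next birth length is exactly
  half the division length, and one daughter is kept deterministically;
* the per-cycle rate is drawn fresh each generation from a Gaussian
  (no mother-daughter inheritance);
* the generation time is computed from the exact growth relation
  (``Td = ln(Ld/Lb)/lambda`` for exponential growth,
  ``Td = (Ld-Lb)/lambda'`` for linear growth), never from the
  first-order expansions used on the theory side;
* degenerate draws (``Ld <= Lb``, ``Td <= 0``, negative size
  increments) are rejected and resampled; the count is carried on the
  returned :class:`~growthmodes.records.Lineage` and a rejection rate
  above 1% aborts the run, since the small-noise regime the models are
  meant for makes such draws negligible;
* per-cycle random draws are consumed in a fixed order (rate first,
  then division-timing noise, then any event noises) so that a seed
  pins down the lineage bit-for-bit.

The default burn-in of 50 discarded generations starts every lineage at
the mean birth length and comfortably reaches the stationary
birth-size law at the noise levels considered (sigma ~ 0.15).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .params import LN2, ConstrictionParams, GrowthMode, ModelParams, NoiseKind, ReplicationParams
from .records import CellCycleRecord, Lineage, Trajectory

_MAX_RETRY = 1000
_MAX_REJECT_FRACTION = 0.01

__all__ = [
    "simulate_lineage",
    "simulate_superexponential_lineage",
    "simulate_adder_per_origin",
    "simulate_constriction_lineage",
    "simulate_population_snapshot",
    "sample_trajectory",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot proceed (e.g. runaway rejections)."""


def _check_rejections(n_rejected: int, n_accepted: int) -> None:
    total = n_rejected + n_accepted
    if total > 0 and n_rejected > _MAX_REJECT_FRACTION * total and n_rejected > 10:
        raise SimulationError(
            f"rejection rate {n_rejected}/{total} exceeds {_MAX_REJECT_FRACTION:.0%}; "
            "noise parameters are outside the small-noise regime"
        )


# ----------------------------------------------------------------------
# single-lineage simulators
# ----------------------------------------------------------------------

def simulate_lineage(
    params: ModelParams,
    n_generations: int,
    burn_in: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Lineage:
    """Simulate a single lineage under exponential or linear growth.

    Division control follows ``f(l_b) = 2 l_b**(1-alpha)`` (exponential)
    or its linearization ``g(l_b) = 2 + 2(1-alpha)(l_b-1)`` (linear) on
    the normalized birth length, with either time-additive or
    size-additive Gaussian timing noise per ``params.noise_kind``.

    Returns ``n_generations`` records taken after ``burn_in`` discarded
    generations.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if params.growth_mode is GrowthMode.SUPER_EXPONENTIAL:
        raise ValueError("use simulate_superexponential_lineage for super-exponential growth")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if params.growth_mode is GrowthMode.EXPONENTIAL:
        step = _exponential_cycle
    else:
        step = _linear_cycle

    mean_lb = params.mean_birth_length
    lb = 1.0  # normalized birth length; start at the mean
    records = Lineage()
    n_rejected = 0
    for gen in range(-burn_in, n_generations):
        for _ in range(_MAX_RETRY):
            result = step(params, lb, rng)
            if result is not None:
                break
            n_rejected += 1
        else:
            raise SimulationError("could not draw a valid cycle after retries")
        ld, td, rate = result
        if gen >= 0:
            records.append(
                CellCycleRecord(
                    generation=gen,
                    Lb=lb * mean_lb,
                    Ld=ld * mean_lb,
                    Td=td,
                    rate=rate,
                )
            )
        lb = ld / 2.0  # perfectly symmetric division
    records.n_rejected = n_rejected
    _check_rejections(n_rejected, burn_in + n_generations)
    return records


def _exponential_cycle(params, lb, rng):
    """One exponential-growth cycle; returns (ld, Td, lambda) or None."""
    lam = params.mean_growth_rate * (1.0 + rng.normal(0.0, params.cv_lambda))
    noise = rng.normal(0.0, 1.0)
    if lam <= 0:
        return None
    if params.noise_kind is NoiseKind.TIME_ADDITIVE:
        td = (LN2 - params.alpha * math.log(lb)) / lam \
            + noise * params.sigma_n / params.mean_growth_rate
        if td <= 0:
            return None
        ld = lb * math.exp(lam * td)
    else:
        ld = 2.0 * lb ** (1.0 - params.alpha) + noise * params.sigma_bd
        if ld <= lb:
            return None
        td = math.log(ld / lb) / lam
    if ld <= lb or td <= 0:
        return None
    return ld, td, lam


def _linear_cycle(params, lb, rng):
    """One linear-growth cycle; returns (ld, Td, elongation speed um/min)."""
    lam_lin = params.mean_elongation_speed_norm * (1.0 + rng.normal(0.0, params.cv_lambda))
    noise = rng.normal(0.0, 1.0)
    if lam_lin <= 0:
        return None
    g = 2.0 + 2.0 * (1.0 - params.alpha) * (lb - 1.0)
    if params.noise_kind is NoiseKind.SIZE_ADDITIVE:
        ld = g + noise * params.sigma_bd
        if ld <= lb:
            return None
        td = (ld - lb) / lam_lin
    else:
        td = (g - lb) / lam_lin + noise * params.sigma_n / params.mean_elongation_speed_norm
        if td <= 0:
            return None
        ld = lb + lam_lin * td
    if ld <= lb or td <= 0:
        return None
    return ld, td, lam_lin * params.mean_birth_length


def simulate_superexponential_lineage(
    params: ModelParams,
    n_generations: int,
    burn_in: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Lineage:
    """Simulate an adder-controlled lineage with super-exponential growth.

    Within each cycle the instantaneous rate is ``lambda_0`` up to the
    crossover time ``t_c = superexp_tc_frac * Td`` and
    ``lambda_0 + k (t - t_c)**2`` afterwards, i.e. the integral of
    ``d lambda/dt = 2 k (t - t_c)``; the log-length therefore grows as
    ``lambda_0 t + k (t - t_c)**3 / 3`` past the crossover.  Division
    size is set by the same strategy ``f(l_b)`` with time-additive
    noise.  With ``superexp_k = 0`` the simulator reduces exactly to the
    exponential one (same seed, same outputs).

    ``params.rate`` on the returned records is the initial rate
    ``lambda_0`` of each cycle.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = params.superexp_k
    f = params.superexp_tc_frac
    c3 = k * (1.0 - f) ** 3 / 3.0
    mean_lb = params.mean_birth_length

    lb = 1.0
    records = Lineage()
    n_rejected = 0
    for gen in range(-burn_in, n_generations):
        for _ in range(_MAX_RETRY):
            lam0 = params.mean_growth_rate * (1.0 + rng.normal(0.0, params.cv_lambda))
            noise = rng.normal(0.0, 1.0)
            dx = LN2 - params.alpha * math.log(lb)  # target log increment
            if lam0 <= 0 or dx <= 0:
                n_rejected += 1
                continue
            t_det = _solve_division_time(lam0, c3, dx)
            td = t_det + noise * params.sigma_n / params.mean_growth_rate
            if td <= 0:
                n_rejected += 1
                continue
            tc = f * td
            ld = lb * math.exp(lam0 * td + k * (td - tc) ** 3 / 3.0)
            if ld > lb:
                break
            n_rejected += 1
        else:
            raise SimulationError("could not draw a valid super-exponential cycle")
        if gen >= 0:
            records.append(
                CellCycleRecord(
                    generation=gen, Lb=lb * mean_lb, Ld=ld * mean_lb, Td=td, rate=lam0
                )
            )
        lb = ld / 2.0
    records.n_rejected = n_rejected
    _check_rejections(n_rejected, burn_in + n_generations)
    return records


def _solve_division_time(lam0: float, c3: float, dx: float) -> float:
    """Positive root of ``lam0*T + c3*T**3 = dx`` (monotone in T)."""
    if c3 == 0.0:
        return dx / lam0
    hi = dx / lam0  # f(hi) >= dx since the cubic term is non-negative
    if lam0 * hi + c3 * hi**3 == dx:
        return hi
    return brentq(lambda t: lam0 * t + c3 * t**3 - dx, 0.0, hi, xtol=1e-12)


def simulate_constriction_lineage(
    params: ModelParams,
    con: ConstrictionParams,
    n_generations: int,
    burn_in: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Lineage:
    """Exponential lineage with a constriction event between birth and division.

    Constriction length ``Ln = Lb + delta_bn`` and division length
    ``Ld = Ln + delta_nd``, both increments Gaussian; records carry
    ``Tn = ln(Ln/Lb)/lambda``.  Negative increments are rejected and
    resampled.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if params.growth_mode is not GrowthMode.EXPONENTIAL:
        raise ValueError("constriction model assumes exponential growth")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    lb_abs = params.mean_birth_length
    records = Lineage()
    n_rejected = 0
    for gen in range(-burn_in, n_generations):
        for _ in range(_MAX_RETRY):
            lam = params.mean_growth_rate * (1.0 + rng.normal(0.0, params.cv_lambda))
            d_bn = rng.normal(con.delta_bn_mean, con.delta_bn_cv * con.delta_bn_mean)
            d_nd = rng.normal(con.delta_nd_mean, con.delta_nd_cv * con.delta_nd_mean)
            if lam <= 0 or d_bn <= 0 or d_nd <= 0:
                n_rejected += 1
                continue
            break
        else:
            raise SimulationError("could not draw valid constriction increments")
        ln_len = lb_abs + d_bn
        ld = ln_len + d_nd
        td = math.log(ld / lb_abs) / lam
        tn = math.log(ln_len / lb_abs) / lam
        if gen >= 0:
            records.append(
                CellCycleRecord(
                    generation=gen, Lb=lb_abs, Ld=ld, Td=td, rate=lam, Tn=tn
                )
            )
        lb_abs = ld / 2.0
    records.n_rejected = n_rejected
    _check_rejections(n_rejected, burn_in + n_generations)
    return records


# ----------------------------------------------------------------------
# adder-per-origin
# ----------------------------------------------------------------------

def simulate_adder_per_origin(
    params: ModelParams,
    rep: ReplicationParams,
    n_generations: int,
    burn_in: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Lineage:
    """Simulate a lineage under the adder-per-origin cell-cycle model.

    Replication initiation fires when the cell length crosses
    ``L_i + O * delta_ii`` (length added per origin since the previous
    initiation, with ``O`` the post-doubling origin count); each
    initiation schedules the corresponding division a C+D period later,
    at which point ``Ld ~= Li * exp(lambda (C+D))`` when the rate is
    unchanged in between.  Growth is exponential with a fresh per-cycle
    rate; origins double at initiation and halve at division; one
    daughter is kept.

    Event times are resolved in closed form under exponential growth and
    snapped up to the ``rep.dt`` grid; when an initiation and a division
    fall on the same grid step the division is applied first.  ``Ti`` on
    a record is the initiation time relative to that cell's birth, and
    is absent when the initiation occurred in the mother.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if params.growth_mode is not GrowthMode.EXPONENTIAL:
        raise ValueError("adder-per-origin model assumes exponential growth")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = rep.dt

    def snap(t: float) -> float:
        return math.ceil(t / dt - 1e-9) * dt

    def draw_rate() -> float:
        for _ in range(_MAX_RETRY):
            lam = params.mean_growth_rate * (1.0 + rng.normal(0.0, params.cv_lambda))
            if lam > 0:
                return lam
        raise SimulationError("could not draw a positive growth rate")

    n_rejected = 0

    # initial condition: birth and initiation at t = 0, two origins
    t = 0.0
    L = params.mean_birth_length
    lam = draw_rate()
    origins = 2
    t_birth = 0.0
    L_birth = L
    origins_at_birth = origins
    ti_this_cycle: Optional[float] = 0.0
    pending: list[dict] = []  # scheduled divisions, time-ordered

    def fire_initiation(t_init: float, L_init: float) -> None:
        nonlocal origins, next_threshold, n_rejected
        origins *= 2
        for _ in range(_MAX_RETRY):
            d_ii = rng.normal(rep.delta_ii_mean, rep.delta_ii_cv * rep.delta_ii_mean)
            if d_ii > 0:
                break
            n_rejected += 1
        else:
            raise SimulationError("could not draw a positive delta_ii")
        next_threshold = L_init + origins * d_ii
        last_div = pending[-1]["t"] if pending else t_init
        for _ in range(_MAX_RETRY):
            cd = rng.normal(rep.cd_mean, rep.cd_cv * rep.cd_mean)
            t_div = snap(t_init + cd)
            if cd > 0 and t_div > last_div and t_div > t_init:
                break
            n_rejected += 1
        else:
            raise SimulationError("could not schedule a valid division")
        pending.append({"t": t_div, "Li": L_init, "cd": t_div - t_init})

    next_threshold = math.inf
    fire_initiation(0.0, L)

    records = Lineage()
    # per recorded division: triggering initiation length (current-lineage
    # units) and the scheduled C+D, for event-bookkeeping cross-checks
    records.division_meta: list[dict] = []
    gen = -burn_in
    while gen < n_generations:
        # time to next initiation crossing under the current rate
        if L >= next_threshold:
            t_init = snap(t)
        else:
            t_init = snap(t + math.log(next_threshold / L) / lam)
        t_div = pending[0]["t"] if pending else math.inf
        if pending and t_div <= t_init:
            # division first on ties
            entry = pending.pop(0)
            L_div = L * math.exp(lam * (entry["t"] - t))
            t = entry["t"]
            if gen >= 0:
                records.append(
                    CellCycleRecord(
                        generation=gen,
                        Lb=L_birth,
                        Ld=L_div,
                        Td=t - t_birth,
                        rate=lam,
                        Ti=ti_this_cycle,
                        n_origins=origins_at_birth,
                    )
                )
                records.division_meta.append(
                    {"Li": entry["Li"], "cd": entry["cd"], "rate": lam}
                )
            gen += 1
            # keep one daughter: halve everything tied to length
            L = L_div / 2.0
            origins //= 2
            next_threshold /= 2.0
            for e in pending:
                e["Li"] /= 2.0
            lam = draw_rate()
            t_birth = t
            L_birth = L
            origins_at_birth = origins
            ti_this_cycle = None
        else:
            L = L * math.exp(lam * (t_init - t))
            t = t_init
            ti_this_cycle = t - t_birth
            fire_initiation(t, L)
    records.n_rejected = n_rejected
    return records


# ----------------------------------------------------------------------
# branching population
# ----------------------------------------------------------------------

def simulate_population_snapshot(
    params: ModelParams,
    n_final: int,
    burn_in: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> Lineage:
    """Grow a branching population (both daughters kept) of exponential cells.

    Cycles are completed breadth-first from a single ancestor until
    ``n_final`` completed cycles have been recorded, after discarding
    the first ``burn_in`` completed cycles as transient.  Used for the
    growth-rate vs inverse-generation-time analyses, where population
    structure (not a single lineage) is the sampled ensemble.
    """
    if n_final < 2:
        raise ValueError("n_final must be >= 2")
    if params.growth_mode is not GrowthMode.EXPONENTIAL:
        raise ValueError("population snapshot assumes exponential growth")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    mean_lb = params.mean_birth_length
    queue = [1.0]  # normalized birth lengths, FIFO over generations
    records = Lineage()
    n_rejected = 0
    completed = 0
    while completed < burn_in + n_final:
        lb = queue.pop(0)
        for _ in range(_MAX_RETRY):
            result = _exponential_cycle(params, lb, rng)
            if result is not None:
                break
            n_rejected += 1
        else:
            raise SimulationError("could not draw a valid cycle after retries")
        ld, td, lam = result
        completed += 1
        if completed > burn_in:
            records.append(
                CellCycleRecord(
                    generation=completed - burn_in - 1,
                    Lb=lb * mean_lb,
                    Ld=ld * mean_lb,
                    Td=td,
                    rate=lam,
                )
            )
        queue.append(ld / 2.0)
        queue.append(ld / 2.0)
    records.n_rejected = n_rejected
    _check_rejections(n_rejected, completed)
    return records


# ----------------------------------------------------------------------
# trajectory sampling
# ----------------------------------------------------------------------

def sample_trajectory(
    cycle: CellCycleRecord,
    params: ModelParams,
    dt: float = 4.0,
    post_division_window: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Sample a cycle's length-vs-time curve on a fixed grid.

    In-cycle samples follow the closed-form growth law of
    ``params.growth_mode`` with the cycle's own rate.  With a positive
    ``post_division_window`` the grid continues past division and the
    samples hold the summed size of the two (equal) daughters; the
    daughters' common rate is one fresh draw from the cycle-rate
    distribution, independent of the mother's (for linear growth the
    fresh draw is the summed object's elongation speed, preserving the
    constant speed-vs-age trend across division).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > cycle.Td:
        raise ValueError("dt larger than the generation time: no in-cycle sample")
    if post_division_window < 0:
        raise ValueError("post_division_window must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed + 7 * (cycle.generation + 1))

    t_max = cycle.Td + post_division_window
    times = np.arange(0.0, t_max + 1e-9, dt)
    in_cycle = times <= cycle.Td + 1e-12
    t_in = times[in_cycle]

    mode = params.growth_mode
    if mode is GrowthMode.EXPONENTIAL:
        lengths_in = cycle.Lb * np.exp(cycle.rate * t_in)
    elif mode is GrowthMode.LINEAR:
        lengths_in = cycle.Lb + cycle.rate * t_in
    else:
        k = params.superexp_k
        tc = params.superexp_tc_frac * cycle.Td
        bump = k * np.clip(t_in - tc, 0.0, None) ** 3 / 3.0
        lengths_in = cycle.Lb * np.exp(cycle.rate * t_in + bump)

    if post_division_window > 0.0:
        t_out = times[~in_cycle]
        s = t_out - cycle.Td
        if mode is GrowthMode.LINEAR:
            total_speed = params.mean_birth_length * params.mean_elongation_speed_norm \
                * (1.0 + rng.normal(0.0, params.cv_lambda))
            lengths_out = cycle.Ld + total_speed * s
        else:
            lam_d = params.mean_growth_rate * (1.0 + rng.normal(0.0, params.cv_lambda))
            lengths_out = cycle.Ld * np.exp(lam_d * s)
        lengths = np.concatenate([lengths_in, lengths_out])
    else:
        lengths = lengths_in
        times = t_in

    return Trajectory(
        cycle_ref=cycle.generation,
        times=times,
        lengths=lengths,
        Td=cycle.Td,
        post_division_window=post_division_window,
        is_extended=post_division_window > 0.0,
    )
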