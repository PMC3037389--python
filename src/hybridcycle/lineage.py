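"""Single-cell life histories: residence times, growth, division, lineages.

A cell is born in G1a (state 1) with known mass and cyclin concentrations and
is followed until it divides at the end of telophase (state 9).  The time in
state *i* is ``T_i = T_det,i + T_stoch,i``: a deterministic execution time
(zero for states 1, 6, 7, 8; a fixed DNA-synthesis floor for state 4; the
threshold-crossing time of the controlling cyclin for states 2, 3, 5, 9) plus
an exponentially distributed waiting time with mean ``lambda_i``.  Because
the kinetics inside a state are linear, every boundary concentration follows
from the closed-form relaxation -- simulating one full cycle costs about a
dozen random numbers and a handful of algebraic evaluations.

Division is near-symmetric: the tracked daughter receives fraction delta (or
1-delta, chosen with probability 1/2) of the mother's mass, with delta drawn
from a Gaussian around 0.5; concentrations pass to the daughter unchanged.
The size-dependent G1b transition ([CycE]*M crossing theta_E) gives the
lineage a stationary birth-size distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .model import (
    ExitCondition,
    UNREACHABLE,
    amount_crossing_time,
    concentration_crossing_time,
    cyclin_at,
)

__all__ = [
    "CellHistory",
    "SimulationError",
    "sample_stochastic_delay",
    "sample_division_asymmetry",
    "residence_time",
    "simulate_cycle",
    "divide",
    "simulate_lineage",
    "histories_to_frame",
]


class SimulationError(RuntimeError):
    """Raised when a cell cannot progress (e.g. an unreachable threshold)."""


@dataclass(frozen=True)
class CellHistory:
    """One cell's complete life history, birth through division.

    ``exit_times[n-1]`` is the absolute time at which the cell left state n;
    ``boundary_conc[n-1]`` holds ([CycA], [CycB], [CycE]) at that moment.
    Concentrations are continuous across boundaries, so the entry value of
    state n+1 equals the exit value of state n.
    """

    birth_time: float
    birth_mass: float
    birth_conc: tuple[float, float, float]
    exit_times: tuple[float, ...]          # length 9, absolute hours
    boundary_conc: tuple[tuple[float, float, float], ...]  # length 9
    t_det: tuple[float, ...]               # deterministic component per state
    t_stoch: tuple[float, ...]             # stochastic component per state
    delta: float                           # division asymmetry drawn at t9

    @property
    def age_at_division(self) -> float:
        """A9 = t9 - t0, hours."""
        return self.exit_times[8] - self.birth_time

    @property
    def s_entry(self) -> float:
        """Absolute time of S-phase entry (exit of late G1b)."""
        return self.exit_times[2]

    @property
    def s_exit(self) -> float:
        """Absolute time of S-phase exit."""
        return self.exit_times[3]

    @property
    def s_duration(self) -> float:
        return self.s_exit - self.s_entry

    def entry_conc(self, n: int) -> tuple[float, float, float]:
        """Concentrations at entry into state n (1..9)."""
        return self.birth_conc if n == 1 else self.boundary_conc[n - 2]

    def entry_time(self, n: int) -> float:
        return self.birth_time if n == 1 else self.exit_times[n - 2]

    def mass_at_age(self, age: float, gamma: float, mode: str = "exponential") -> float:
        """Mass at a given age, matching the growth law used in simulation."""
        if mode == "exponential":
            return self.birth_mass * math.exp(gamma * age)
        return self.birth_mass * (1.0 + gamma * age)


def sample_stochastic_delay(lam: float, rng: np.random.Generator) -> float:
    """One exponential waiting time with mean ``lam`` hours (0 if lam == 0).

    Uses the inversion formula -lam*ln(r) with r uniform on (0, 1].
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam == 0.0:
        return 0.0
    r = 1.0 - rng.random()  # uniform on (0, 1]
    return -lam * math.log(r)


def _crossing_time(
    cstate: dict,
    conc: tuple[float, float, float],
    mass_entry: float,
    gamma_eff: float,
    theta: float,
    growth_mode: str,
    birth_mass: float,
    age_entry: float,
) -> float:
    """Deterministic time to the controlling threshold from state entry."""
    spec = cstate["spec"]
    thr = spec.threshold
    idx = {"A": 0, "B": 1, "E": 2}[thr.cyclin.value]
    c0 = conc[idx]
    ks, kd = cstate["rates"][thr.cyclin.value]
    if thr.basis == "concentration":
        return concentration_crossing_time(c0, ks, kd, theta, thr.direction)
    if growth_mode == "exponential":
        return amount_crossing_time(c0, ks, kd, mass_entry, gamma_eff, theta, thr.direction)
    # Linear growth: M(t) = M_b*(1 + gamma*age); solve on a shifted-time scan.
    rate = gamma_eff * birth_mass

    def amount(t: float) -> float:
        return cyclin_at(c0, ks, kd, t) * (mass_entry + rate * t)

    sign = 1.0 if thr.direction.value == "up" else -1.0
    if sign * (amount(0.0) - theta) >= 0.0:
        return 0.0
    step = 0.1 / max(kd, gamma_eff, 1.0)
    lo = 0.0
    t = step
    horizon = 400.0 / min(kd, gamma_eff)
    from scipy.optimize import brentq
    while t <= horizon:
        if sign * (amount(t) - theta) >= 0.0:
            return brentq(lambda u: sign * (amount(u) - theta), lo, t, xtol=1e-10)
        lo = t
        t += step
    return UNREACHABLE


def residence_time(
    cstate: dict,
    conc: tuple[float, float, float],
    mass_entry: float,
    config: ModelConfig,
    rng: np.random.Generator,
    *,
    theta_factor: float = 1.0,
    birth_mass: float | None = None,
    age_entry: float = 0.0,
    lam_override: float | None = None,
) -> tuple[float, float, float]:
    """Total residence time in one state: (T_i, T_det, T_stoch).

    ``theta_factor`` is the per-cycle Gaussian threshold-noise factor G
    applied multiplicatively to the state's threshold.  ``lam_override``
    replaces the state's waiting-time mean (used by the contact-inhibition
    simulation, which sets lambda_1 = 1/p(N)).
    """
    spec = cstate["spec"]
    if spec.exit_condition is ExitCondition.TIMER:
        t_det = spec.t_det
    else:
        theta = cstate["theta"] * theta_factor
        t_det = _crossing_time(
            cstate, conc, mass_entry, config.gamma, theta,
            config.growth_mode, birth_mass or mass_entry, age_entry,
        )
        if not math.isfinite(t_det):
            raise SimulationError(
                f"state {spec.index} ({spec.phase}): threshold "
                f"{spec.threshold.theta_key}={theta:.4g} on cyclin "
                f"{spec.threshold.cyclin.value} is unreachable from "
                f"conc={conc}, mass={mass_entry:.4g}"
            )
    lam = spec.lam if lam_override is None else lam_override
    t_stoch = sample_stochastic_delay(lam, rng)
    return t_det + t_stoch, t_det, t_stoch


def sample_division_asymmetry(config: ModelConfig, rng: np.random.Generator) -> float:
    """One division-asymmetry draw: Gaussian(delta_mean, delta_sd), clipped.

    Clipping to the configured window guards against Gaussian tail draws
    outside (0, 1); at the default SD of 0.0167 a clip is a ~24-sigma event,
    so in practice the window never binds.
    """
    if config.delta_sd == 0.0:
        return config.delta_mean
    delta = config.delta_mean + config.delta_sd * rng.standard_normal()
    lo, hi = config.delta_clip
    return min(max(delta, lo), hi)


def divide(
    history: CellHistory,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Split the mother at t9; return (tracked daughter mass, delta).

    The mother's division mass M(t9) splits into delta*M and (1-delta)*M
    using the asymmetry stored on the history; the tracked daughter is one
    of the two at random, so it receives delta*M or (1-delta)*M with
    probability 1/2 each.  Mass is conserved: the two shares sum to M(t9).
    """
    m_div = history.mass_at_age(history.age_at_division, config.gamma,
                                config.growth_mode)
    delta = history.delta
    if config.delta_sd > 0.0 and rng.random() < 0.5:
        frac = 1.0 - delta
    else:
        frac = delta
    return frac * m_div, delta


def simulate_cycle(
    birth_time: float,
    birth_mass: float,
    birth_conc: tuple[float, float, float],
    config: ModelConfig,
    rng: np.random.Generator,
    *,
    compiled: list[dict] | None = None,
    lam1_override: float | None = None,
    t1_stoch_override: float | None = None,
) -> CellHistory:
    """Simulate one full cycle (states 1..9) and return the CellHistory.

    The division asymmetry delta is drawn here (at t9) and stored on the
    history; callers use :func:`divide` or the stored delta to seed the next
    generation.  ``lam1_override`` substitutes the G1a waiting-time mean for
    this cell only; ``t1_stoch_override`` injects an externally drawn G1a
    waiting time verbatim (the contact-inhibition simulator draws it against
    the density-dependent exit rate before deciding whether the cell will
    progress at all).
    """
    if birth_mass <= 0 or any(c < 0 for c in birth_conc):
        raise ValueError("birth mass must be > 0 and concentrations >= 0")
    cstates = compiled if compiled is not None else config.compiled_states()
    gamma = config.gamma
    exp_growth = config.growth_mode == "exponential"

    # Per-cycle threshold noise: one Gaussian factor per threshold key.
    if config.threshold_sd > 0.0:
        factors = {k: 1.0 + config.threshold_sd * rng.standard_normal()
                   for k in config.thresholds}
    else:
        factors = {k: 1.0 for k in config.thresholds}

    t = birth_time
    conc = birth_conc
    exit_times: list[float] = []
    boundary: list[tuple[float, float, float]] = []
    t_dets: list[float] = []
    t_stochs: list[float] = []

    for cstate in cstates:
        spec = cstate["spec"]
        age = t - birth_time
        mass_entry = (birth_mass * math.exp(gamma * age) if exp_growth
                      else birth_mass * (1.0 + gamma * age))
        tf = (factors[spec.threshold.theta_key]
              if spec.exit_condition is ExitCondition.THRESHOLD else 1.0)
        if spec.index == 1 and t1_stoch_override is not None:
            t_i, t_det, t_stoch = t1_stoch_override, 0.0, t1_stoch_override
        else:
            t_i, t_det, t_stoch = residence_time(
                cstate, conc, mass_entry, config, rng,
                theta_factor=tf, birth_mass=birth_mass, age_entry=age,
                lam_override=lam1_override if spec.index == 1 else None,
            )
        r = cstate["rates"]
        conc = (
            cyclin_at(conc[0], *r["A"], t_i),
            cyclin_at(conc[1], *r["B"], t_i),
            cyclin_at(conc[2], *r["E"], t_i),
        )
        t += t_i
        exit_times.append(t)
        boundary.append(conc)
        t_dets.append(t_det)
        t_stochs.append(t_stoch)

    delta = sample_division_asymmetry(config, rng)

    return CellHistory(
        birth_time=birth_time,
        birth_mass=birth_mass,
        birth_conc=birth_conc,
        exit_times=tuple(exit_times),
        boundary_conc=tuple(boundary),
        t_det=tuple(t_dets),
        t_stoch=tuple(t_stochs),
        delta=delta,
    )


def simulate_lineage(
    n_total: int,
    n_burnin: int,
    config: ModelConfig,
    rng: np.random.Generator,
) -> list[CellHistory]:
    """Follow a single lineage for ``n_total`` generations, discard the first
    ``n_burnin``, and return the remaining histories.

    The progenitor starts from the configured initial conditions; after each
    division one of the two daughters is chosen at random (tracked mass
    delta*M or (1-delta)*M with probability 1/2) and inherits the mother's
    boundary concentrations.  Burn-in lets the birth-mass distribution reach
    its stationary form under theta_E size control before cells are kept.
    """
    if not n_total > n_burnin >= 0:
        raise ValueError("need n_total > n_burnin >= 0")
    compiled = config.compiled_states()
    mass = config.initial_mass
    conc = config.initial_conc
    t = 0.0
    out: list[CellHistory] = []
    for i in range(n_total):
        hist = simulate_cycle(t, mass, conc, config, rng, compiled=compiled)
        if i >= n_burnin:
            out.append(hist)
        mass, _ = divide(hist, config, rng)
        conc = hist.boundary_conc[8]
        t = hist.exit_times[8]
    return out


def histories_to_frame(histories: list[CellHistory]):
    """Tabulate histories, one row per cell (TSV-ready; documented order)."""
    import pandas as pd

    rows = []
    for i, h in enumerate(histories):
        row = {"cell": i, "t_0": h.birth_time, "mass_birth": h.birth_mass}
        for n in range(1, 10):
            row[f"t_{n}"] = h.exit_times[n - 1]
        for n in range(1, 10):
            ca, cb, ce = h.boundary_conc[n - 1]
            row[f"cycA_t{n}"] = ca
            row[f"cycB_t{n}"] = cb
            row[f"cycE_t{n}"] = ce
        row["delta"] = h.delta
        row["age_division"] = h.age_at_division
        rows.append(row)
    return pd.DataFrame(rows)
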