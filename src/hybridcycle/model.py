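"""Core machinery of the hybrid cell-cycle model.

The model tracks three cyclins (A, B, E) as continuous concentrations obeying
piecewise-linear kinetics d[CycX]/dt = ks_x - kd_x*[CycX], while the cyclin
regulators -- two transcription factors (TFE, TFB) and four ubiquitination
activities (SCF, Cdc20A, Cdc20B, Cdh1) -- are Boolean flags that traverse a
fixed nine-state sequence each cycle (the "super highway"): G1a, early G1b,
late G1b, S, G2, prophase, prometaphase/metaphase, anaphase, telophase.
Within a state the rate constants are fixed by the Boolean vector, so every
cyclin trajectory is an exact exponential relaxation and threshold-crossing
times are available in closed form (or by one-dimensional root finding when
the threshold is on a cyclin *amount*, concentration times growing mass).

Nothing here integrates an ODE numerically; numerical integration appears
only as an independent oracle in the test suite.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "Cyclin",
    "BooleanRegulators",
    "CyclinRates",
    "CyclinRateParams",
    "ExitCondition",
    "Direction",
    "ThresholdSpec",
    "StateSpec",
    "UNREACHABLE",
    "PHASE_OF_STATE",
    "default_state_table",
    "effective_rates",
    "cyclin_at",
    "mass_at",
    "concentration_crossing_time",
    "amount_crossing_time",
]


class Cyclin(str, enum.Enum):
    A = "A"
    B = "B"
    E = "E"


class ExitCondition(str, enum.Enum):
    TIMER = "timer"
    THRESHOLD = "threshold"


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"


#: Sentinel returned by crossing-time solvers when the trajectory can never
#: attain the threshold (theta on the wrong side of the asymptote ks/kd).
UNREACHABLE = math.inf


@dataclass(frozen=True)
class BooleanRegulators:
    """On/off state of the six cyclin regulators in one model state."""

    tfe: int = 0
    tfb: int = 0
    scf: int = 0
    cdc20a: int = 0
    cdc20b: int = 0
    cdh1: int = 0

    def __post_init__(self) -> None:
        for name in ("tfe", "tfb", "scf", "cdc20a", "cdc20b", "cdh1"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"regulator {name} must be 0 or 1, got {v!r}")


@dataclass(frozen=True)
class CyclinRates:
    """Synthesis/degradation constants for one cyclin.

    ``ks`` terms are in concentration/h, ``kd`` terms in 1/h.  Couplings a
    cyclin does not have (e.g. SCF acting on cyclin A) are simply zero.
    """

    ks_basal: float = 0.0
    ks_tfe: float = 0.0
    ks_tfb: float = 0.0
    kd_basal: float = 0.0
    kd_scf: float = 0.0
    kd_cdc20a: float = 0.0
    kd_cdc20b: float = 0.0
    kd_cdh1: float = 0.0

    def __post_init__(self) -> None:
        bad = [k for k, v in self.__dict__.items() if v < 0]
        if bad:
            raise ValueError(f"rate constants must be >= 0: {bad}")


@dataclass(frozen=True)
class CyclinRateParams:
    """Rate constants for all three cyclins."""

    a: CyclinRates
    b: CyclinRates
    e: CyclinRates

    def for_cyclin(self, cyclin: Cyclin | str) -> CyclinRates:
        return {"A": self.a, "B": self.b, "E": self.e}[str(Cyclin(cyclin).value)]


@dataclass(frozen=True)
class ThresholdSpec:
    """Which cyclin threshold ends a state, on what basis, in which direction."""

    cyclin: Cyclin
    theta_key: str               # key into ModelConfig.thresholds
    basis: str                   # "concentration" | "amount" ([CycX]*M)
    direction: Direction

    def __post_init__(self) -> None:
        if self.basis not in ("concentration", "amount"):
            raise ValueError(f"unknown threshold basis {self.basis!r}")


@dataclass(frozen=True)
class StateSpec:
    """One row of the nine-state table."""

    index: int
    phase: str
    regulators: BooleanRegulators
    exit_condition: ExitCondition
    threshold: ThresholdSpec | None = None
    t_det: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 9:
            raise ValueError(f"state index must be 1..9, got {self.index}")
        if self.t_det < 0 or self.lam < 0:
            raise ValueError("t_det and lam must be >= 0")
        if self.exit_condition is ExitCondition.THRESHOLD and self.threshold is None:
            raise ValueError(f"state {self.index}: threshold exit needs a ThresholdSpec")
        if self.exit_condition is ExitCondition.TIMER and self.threshold is not None:
            raise ValueError(f"state {self.index}: timer exit must not carry a threshold")


#: Cytometric phase label per model state (G1a + both G1b sub-states -> G0/G1,
#: the S state -> S, everything from G2 through telophase -> G2/M).
PHASE_OF_STATE = {
    1: "G0/G1", 2: "G0/G1", 3: "G0/G1",
    4: "S",
    5: "G2/M", 6: "G2/M", 7: "G2/M", 8: "G2/M", 9: "G2/M",
}


def default_state_table(lambdas: list[float], t_det_s: float = 7.0) -> list[StateSpec]:
    """Build the canonical nine-state sequence.

    Regulator timing: TFE is on from the restriction point through S (states
    2-4); SCF is on from S entry until division (4-9); TFB is on from G2
    through anaphase (5-8); Cdc20A acts in prometaphase and anaphase (7-8);
    Cdc20B only at anaphase (8); Cdh1 is on in G1a/early G1b (1-2) and again
    in telophase (9).

    States 2, 3, 5 and 9 end when a cyclin variable crosses its threshold;
    states 1, 6, 7, 8 have no deterministic component at all, and the S state
    has a fixed deterministic floor ``t_det_s``.
    """
    if len(lambdas) != 9:
        raise ValueError("need exactly 9 waiting-time means")
    R = BooleanRegulators
    up, down = Direction.UP, Direction.DOWN
    thr = ThresholdSpec
    rows = [
        StateSpec(1, "G1a", R(cdh1=1), ExitCondition.TIMER, lam=lambdas[0]),
        StateSpec(2, "G1b-early", R(tfe=1, cdh1=1), ExitCondition.THRESHOLD,
                  thr(Cyclin.E, "theta_e", "amount", up), lam=lambdas[1]),
        StateSpec(3, "G1b-late", R(tfe=1), ExitCondition.THRESHOLD,
                  thr(Cyclin.A, "theta_a", "concentration", up), lam=lambdas[2]),
        StateSpec(4, "S", R(tfe=1, scf=1), ExitCondition.TIMER,
                  t_det=t_det_s, lam=lambdas[3]),
        StateSpec(5, "G2", R(scf=1, tfb=1), ExitCondition.THRESHOLD,
                  thr(Cyclin.B, "theta_b_hi", "concentration", up), lam=lambdas[4]),
        StateSpec(6, "prophase", R(scf=1, tfb=1), ExitCondition.TIMER, lam=lambdas[5]),
        StateSpec(7, "prometa/metaphase", R(scf=1, tfb=1, cdc20a=1),
                  ExitCondition.TIMER, lam=lambdas[6]),
        StateSpec(8, "anaphase", R(scf=1, tfb=1, cdc20a=1, cdc20b=1),
                  ExitCondition.TIMER, lam=lambdas[7]),
        StateSpec(9, "telophase", R(scf=1, cdh1=1), ExitCondition.THRESHOLD,
                  thr(Cyclin.B, "theta_b_lo", "concentration", down), lam=lambdas[8]),
    ]
    return rows


def effective_rates(
    cyclin: Cyclin | str,
    regs: BooleanRegulators,
    params: CyclinRateParams,
) -> tuple[float, float]:
    """Effective (ks, kd) for one cyclin under a given Boolean regulator vector.

    ks is the basal synthesis rate plus every transcription-factor increment
    whose flag is on; kd is the basal degradation rate plus every
    ubiquitination increment whose flag is on.

    Raises ``ValueError`` if the effective kd is zero: the closed-form
    solution divides by kd, so each state must have some degradation route.
    """
    r = params.for_cyclin(cyclin)
    ks = r.ks_basal + regs.tfe * r.ks_tfe + regs.tfb * r.ks_tfb
    kd = (r.kd_basal + regs.scf * r.kd_scf + regs.cdc20a * r.kd_cdc20a
          + regs.cdc20b * r.kd_cdc20b + regs.cdh1 * r.kd_cdh1)
    if kd <= 0.0:
        raise ValueError(
            f"effective degradation rate for cyclin {Cyclin(cyclin).value} is 0 "
            f"under regulators {regs}; the analytic solution requires kd > 0"
        )
    return ks, kd


def cyclin_at(c0: float, ks: float, kd: float, dt: float) -> float:
    """Concentration after ``dt`` hours of linear synthesis/degradation kinetics.

    Exact solution of dC/dt = ks - kd*C:
    ``C(dt) = ks/kd + (C0 - ks/kd) * exp(-kd*dt)``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    css = ks / kd
    return css + (c0 - css) * math.exp(-kd * dt)


def mass_at(m0: float, gamma: float, dt: float) -> float:
    """Mass after ``dt`` hours of exponential growth at specific rate gamma (1/h)."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return m0 * math.exp(gamma * dt)


def _check_direction(current: float, theta: float, direction: Direction) -> float | None:
    """0.0 if the threshold is already met at t=0 in the stated direction, else None."""
    if direction is Direction.UP and current >= theta:
        return 0.0
    if direction is Direction.DOWN and current <= theta:
        return 0.0
    return None


def concentration_crossing_time(
    c0: float,
    ks: float,
    kd: float,
    theta: float,
    direction: Direction | str = Direction.UP,
) -> float:
    """Smallest t >= 0 with C(t) = theta, in hours, or ``UNREACHABLE``.

    C(t) relaxes monotonically from c0 toward the asymptote ks/kd, so the
    crossing time inverts in closed form:
    ``t = (1/kd) * ln((c0 - ks/kd) / (theta - ks/kd))``.
    A threshold on the far side of the asymptote is never reached. A cell
    already past the threshold at state entry gets crossing time 0 (the
    fixed state sequence only ever moves forward).
    """
    direction = Direction(direction)
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    hit = _check_direction(c0, theta, direction)
    if hit is not None:
        return hit
    css = ks / kd
    # Reachability: theta must lie strictly between c0 and the asymptote.
    if (theta - css) * (c0 - css) <= 0 or abs(theta - css) >= abs(c0 - css):
        return UNREACHABLE
    return math.log((c0 - css) / (theta - css)) / kd


def amount_crossing_time(
    c0: float,
    ks: float,
    kd: float,
    m0: float,
    gamma: float,
    theta: float,
    direction: Direction | str = Direction.UP,
    *,
    xtol: float = 1e-10,
) -> float:
    """Smallest t >= 0 with C(t)*M(t) = theta (amount basis), or ``UNREACHABLE``.

    The amount A(t) = M0*exp(gamma*t)*[ks/kd + (c0-ks/kd)*exp(-kd*t)] is
    transcendental in t; the first crossing is bracketed by forward scanning
    and refined with Brent's method to ``xtol`` hours.  With gamma = 0 this
    reduces exactly to ``concentration_crossing_time`` with theta/m0.
    """
    direction = Direction(direction)
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if m0 <= 0:
        raise ValueError(f"m0 must be > 0, got {m0}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if gamma == 0.0:
        return concentration_crossing_time(c0, ks, kd, theta / m0, direction)

    hit = _check_direction(c0 * m0, theta, direction)
    if hit is not None:
        return hit

    def amount(t: float) -> float:
        return cyclin_at(c0, ks, kd, t) * mass_at(m0, gamma, t)

    sign = 1.0 if direction is Direction.UP else -1.0

    def f(t: float) -> float:
        return sign * (amount(t) - theta)

    # Forward scan on a step resolving both time scales; the amount has at
    # most one interior extremum, so the first sign change brackets the first
    # crossing once the step is well below 1/kd and 1/gamma.
    step = 0.1 / max(kd, gamma, 1.0)
    # Hard horizon: if growing (ks>0, gamma>0) the amount diverges; bound the
    # scan by the time for pure growth from the smallest possible amount to
    # exceed theta by a wide margin, plus relaxation time.
    lo, flo = 0.0, f(0.0)
    horizon = 200.0 / min(kd, gamma) if ks > 0 else 200.0 / kd
    t = step
    while t <= horizon:
        ft = f(t)
        if ft >= 0.0:
            return brentq(f, lo, t, xtol=xtol)
        lo, flo = t, ft
        t += step
    return UNREACHABLE
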