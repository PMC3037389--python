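"""Contact-inhibited population growth: density-dependent G1a exit.

Models a culture expanding from a small seed toward confluence.  Every cell
runs the same nine-state cycle as the lineage simulator, but the mean of the
exponential G1a waiting time is set per cell at birth to 1/p(N), where the
G1a exit rate p falls sigmoidally with the number of live cells N:

    p(N) = p0 / (1 + exp((N - N0) / N1))

With 0 < N1 << N0 this drops abruptly from p0 to 0 as N passes N0, so the
population grows exponentially while sparse and arrests in G1a (a quiescent,
G0-like state) at confluence.  Both daughters are tracked (a full binary
tree of lineages, unlike the single-lineage sampler), there is no cell
death, and the culture is snapshotted every 24 h for counts and G0/G1, S,
G2/M phase fractions.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ContactInhibitionParams, ModelConfig
from .lineage import CellHistory, SimulationError, sample_stochastic_delay, simulate_cycle
from .model import PHASE_OF_STATE

__all__ = [
    "transition_probability",
    "phase_fractions",
    "simulate_contact_inhibition",
    "PopulationResult",
]


def transition_probability(n_cells: float, params: ContactInhibitionParams) -> float:
    """G1a exit rate p(N) in 1/h; strictly decreasing, p(0) ~= p0, -> 0 for N >> N0."""
    if n_cells < 0:
        raise ValueError("cell count must be >= 0")
    x = (n_cells - params.n_half) / params.n_width
    # Guard the exp against overflow for very large populations.
    if x > 700.0:
        return params.p0 * math.exp(-x)  # asymptotically exact, avoids overflow
    return params.p0 / (1.0 + math.exp(x))


def phase_fractions(states: list[int] | np.ndarray) -> tuple[float, float, float]:
    """Percentages (G0/G1, S, G2/M) for a population snapshot of state indices."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty population snapshot")
    n = states.size
    g01 = np.count_nonzero(states <= 3) / n * 100.0
    s = np.count_nonzero(states == 4) / n * 100.0
    g2m = np.count_nonzero(states >= 5) / n * 100.0
    return g01, s, g2m


@dataclass
class _Cell:
    birth_time: float
    birth_mass: float
    history: CellHistory
    version: int = 0           # bumped when the pending cycle is re-scheduled

    def state_at(self, t: float) -> int:
        """State occupied at absolute time t (t >= birth_time)."""
        times = self.history.exit_times
        lo, hi = 0, 9
        while lo < hi:
            mid = (lo + hi) // 2
            if times[mid] <= t:
                lo = mid + 1
            else:
                hi = mid
        return min(lo + 1, 9)


@dataclass
class PopulationResult:
    """Daily growth curve plus the final population."""

    curve: pd.DataFrame                      # day, count, pct_g0g1, pct_s, pct_g2m
    final_states: np.ndarray = field(repr=False, default=None)

    @property
    def counts(self) -> np.ndarray:
        return self.curve["count"].to_numpy()

    def plateau_day(self, rel_increase: float = 0.05) -> int:
        """First day whose count grew by less than ``rel_increase`` over the
        previous day's count."""
        c = self.counts
        for d in range(1, len(c)):
            if c[d] < (1.0 + rel_increase) * c[d - 1]:
                return int(self.curve["day"].iloc[d])
        raise ValueError("population never plateaued within the simulated horizon")


def simulate_contact_inhibition(
    params: ContactInhibitionParams,
    config: ModelConfig,
    rng: np.random.Generator,
    *,
    reevaluate_daily: bool = False,
) -> PopulationResult:
    """Event-driven simulation of a contact-inhibited culture.

    Starts ``params.n_init`` independent cells at t = 0 from the configured
    initial conditions and follows every descendant until day ``params.days``.
    When a cell is born (enters G1a) its whole cycle is drawn immediately,
    with the G1a waiting-time mean set to 1/p(N) at the instantaneous
    population size N; divisions are then processed in chronological order,
    each one replacing the mother by two daughters and incrementing N by 1.

    With ``reevaluate_daily`` cells still waiting in G1a at a daily snapshot
    redraw their residual wait at the current p(N) (memorylessness makes this
    a clean restart); by default a drawn wait is kept, which only mildly
    affects how sharply the plateau sets in.
    """
    params.validate()
    compiled = config.compiled_states()
    horizon = params.days * 24.0
    t_now = 0.0
    n_alive = params.n_init

    def park(birth_time: float, birth_mass: float, conc, wait: float) -> CellHistory:
        """A cell whose G1a exit falls beyond the horizon: freeze it in state 1.

        Exit times are all set past the horizon so the cell reads as G1a
        (quiescent/G0) at every remaining snapshot; its post-arrest cycle is
        never needed within the simulated window.
        """
        return CellHistory(
            birth_time=birth_time, birth_mass=birth_mass, birth_conc=tuple(conc),
            exit_times=(birth_time + wait,) + (math.inf,) * 8,
            boundary_conc=(tuple(conc),) * 9,
            t_det=(0.0,) * 9, t_stoch=(wait,) + (0.0,) * 8,
            delta=config.delta_mean,
        )

    def make_cell(birth_time: float, birth_mass: float, conc, n_current: int,
                  *, extra_wait: float = 0.0) -> _Cell:
        """Create a cell and draw its full cycle at the current density.

        The G1a waiting time is drawn from Exp(1/p(N)); ``extra_wait`` is
        G1a time already served (used when a wait is redrawn at a snapshot).
        """
        p = transition_probability(n_current, params)
        wait = (sample_stochastic_delay(1.0 / p, rng) if p > 0 else math.inf)
        total_wait = extra_wait + wait
        if birth_time + total_wait > horizon:
            hist = park(birth_time, birth_mass, conc, total_wait)
        else:
            hist = simulate_cycle(birth_time, birth_mass, conc, config, rng,
                                  compiled=compiled, t1_stoch_override=total_wait)
        return _Cell(birth_time, birth_mass, hist)

    heap: list[tuple[float, int, int, _Cell]] = []
    serial = 0
    cells: set[int] = set()
    registry: dict[int, _Cell] = {}

    def schedule(cell: _Cell) -> None:
        nonlocal serial
        serial += 1
        registry[serial] = cell
        cells.add(serial)
        if math.isfinite(cell.history.exit_times[8]):
            heapq.heappush(heap, (cell.history.exit_times[8], cell.version, serial, cell))

    for _ in range(params.n_init):
        schedule(make_cell(0.0, config.initial_mass, config.initial_conc, n_alive))

    days, counts, f_g01, f_s, f_g2m = [], [], [], [], []

    def snapshot(day: int, t_snap: float) -> None:
        states = [registry[cid].state_at(t_snap) for cid in cells]
        g01, s, g2m = phase_fractions(states)
        days.append(day)
        counts.append(len(cells))
        f_g01.append(g01)
        f_s.append(s)
        f_g2m.append(g2m)

    def reevaluate(t_snap: float) -> None:
        """Redraw the residual G1a wait of every cell still in G1a at the
        current density (exponential memorylessness makes this a clean
        restart); the rest of the cycle is re-simulated from the new exit."""
        for cid in list(cells):
            cell = registry[cid]
            h = cell.history
            if h.exit_times[0] <= t_snap:   # already past G1a
                continue
            served = t_snap - cell.birth_time
            fresh = make_cell(cell.birth_time, cell.birth_mass, h.birth_conc,
                              n_alive, extra_wait=served)
            cell.history = fresh.history
            cell.version += 1
            if math.isfinite(cell.history.exit_times[8]):
                heapq.heappush(heap, (cell.history.exit_times[8],
                                      cell.version, cid, cell))

    next_day = 0
    while next_day <= params.days:
        t_snap = next_day * 24.0
        # Process divisions up to the snapshot time.
        while heap and heap[0][0] <= t_snap:
            t_div, version, cid, cell = heapq.heappop(heap)
            if cid not in cells or version != cell.version:
                continue  # stale entry (cell already divided or re-scheduled)
            cells.discard(cid)
            del registry[cid]
            n_alive -= 1
            h = cell.history
            m_div = h.mass_at_age(h.age_at_division, config.gamma, config.growth_mode)
            conc = h.boundary_conc[8]
            for frac in (h.delta, 1.0 - h.delta):
                n_alive += 1
                schedule(make_cell(t_div, frac * m_div, conc, n_alive))
            if n_alive > params.hard_cap:
                raise SimulationError(
                    f"population exceeded hard cap {params.hard_cap} at t={t_div:.1f} h"
                )
        snapshot(next_day, t_snap)
        if reevaluate_daily:
            reevaluate(t_snap)
        next_day += 1

    final_states = np.array([registry[cid].state_at(horizon) for cid in cells])
    curve = pd.DataFrame({
        "day": days, "count": counts,
        "pct_g0g1": f_g01, "pct_s": f_s, "pct_g2m": f_g2m,
    })
    return PopulationResult(curve=curve, final_states=final_states)
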