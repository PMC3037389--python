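"""Grow a culture from 500 cells to confluence under contact inhibition.

The G1a exit rate falls sigmoidally with the live-cell count,
p(N) = p0 / (1 + exp((N - N0)/N1)) with p0 = 0.5/h, N0 = 11,000, N1 = 500,
so the culture expands exponentially while sparse (about 2x per day at a
20 h mean cycle) and arrests in G1a -- a quiescent, G0-like state -- as N
passes N0.  Cells already past G1a when the brake engages still finish
their cycle, which is why the plateau overshoots N0.
"""

import numpy as np

from hybridcycle import default_config, simulate_contact_inhibition

cfg = default_config()
res = simulate_contact_inhibition(cfg.contact_inhibition, cfg,
                                  np.random.default_rng(1))

print(res.curve.round(1).to_string(index=False))
day = res.plateau_day(0.05)
print(f"\nplateau (first day with <5% daily increase): day {day}")
print(f"final count {int(res.counts[-1])}; "
      f"{(res.final_states == 1).mean() * 100:.1f}% of cells arrested in G1a/G0")
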