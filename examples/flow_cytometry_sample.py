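"""Simulate an asynchronous flow-cytometry experiment and summarize it.

Generates 32,000 post-burn-in life histories along a single lineage, fixes
each cell at a random cycle fraction phi (density proportional to 2^-phi:
newborns twice as dense as dividers), reads out DNA content and total cyclin
A/B/E with multiplicative instrument noise, and prints the summary numbers a
cytometrist would look at first.  Pass --plot to also write scatter PNGs
(requires matplotlib) into ./scratch.
"""

import argparse

import numpy as np

from hybridcycle import default_config, simulate_flow_sample, simulate_lineage

parser = argparse.ArgumentParser()
parser.add_argument("--plot", action="store_true")
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

cfg = default_config()
rng = np.random.default_rng(args.seed)

histories = simulate_lineage(32_500, 500, cfg, rng)
events = simulate_flow_sample(histories, cfg, rng)

frac = events["phase"].value_counts(normalize=True) * 100
print(f"events: {len(events)}   phase fractions:  "
      f"G0/G1 {frac['G0/G1']:.1f}%   S {frac['S']:.1f}%   G2/M {frac['G2/M']:.1f}%")

dna_sd = (events["dna_meas"] / events["dna_true"]).std()
cyc_sd = (events["cycA_meas"] / events["cycA_true"]).std()
print(f"recovered instrument noise: DNA {dna_sd:.3f} (true 0.03), "
      f"cyclin {cyc_sd:.3f} (true 0.15)")

tot_a = np.array([h.boundary_conc[2][0]
                  * h.mass_at_age(h.s_entry - h.birth_time, cfg.gamma)
                  for h in histories])
q99 = np.percentile(events["cycA_true"], 99)
print(f"total cyclin A at S entry: mean {tot_a.mean():.1f} a.u. = "
      f"{100 * tot_a.mean() / q99:.1f}% of the population maximum "
      f"({q99:.0f} a.u., 99th percentile)")

if args.plot:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from hybridcycle.plotting import cyclin_loop, scatter_dna_vs_cyclin

    Path("scratch").mkdir(exist_ok=True)
    for cyc in ("A", "B", "E"):
        ax = scatter_dna_vs_cyclin(events, cyc)
        ax.figure.savefig(f"scratch/dna_vs_cyclin{cyc}.png", dpi=150)
        plt.close(ax.figure)
    ax = cyclin_loop(events)
    ax.figure.savefig("scratch/cyclin_loop.png", dpi=150)
    print("wrote scatter plots to scratch/")
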