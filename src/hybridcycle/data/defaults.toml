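# Default model configuration for the hybrid cell-cycle simulator.
#
# Every key carries a provenance tag:
#   paper      - published value of the model
#   calibrated - chosen once here to meet the documented calibration targets
#                (mean cycle length ~= 20 h; total cyclin A at S entry ~= 8%
#                of the 99th-percentile total cyclin A in an asynchronous
#                population; cyclin B drops partially at anaphase and is then
#                fully degraded in telophase). See docs/methods.md.
#
# Units: concentrations are model units (AU); rates in AU/h or 1/h; times in h.

[rates.cyclin_a]
ks_basal = 5.0     # provenance: paper (k'_sa = 5)
ks_tfe = 5.0       # provenance: calibrated (modest rise while Cdh1 active)
ks_tfb = 10.0      # provenance: calibrated
kd_basal = 0.05    # provenance: calibrated
kd_cdc20a = 4.0    # provenance: calibrated (precipitous drop in prometaphase)
kd_cdh1 = 1.35     # provenance: calibrated; kd_basal + kd_cdh1 = 1.4 is paper

[rates.cyclin_b]
ks_basal = 1.0     # provenance: calibrated (modest rise in late G1/S)
ks_tfb = 39.0      # provenance: calibrated (rapid accumulation in G2)
kd_basal = 0.05    # provenance: calibrated
kd_cdc20b = 1.5    # provenance: calibrated (partial degradation at anaphase)
kd_cdh1 = 3.0      # provenance: calibrated (faster degradation in telophase)

[rates.cyclin_e]
ks_basal = 0.1     # provenance: calibrated
ks_tfe = 2.0       # provenance: calibrated
kd_basal = 0.2     # provenance: calibrated
kd_scf = 1.0       # provenance: calibrated (cyclin E degraded in S phase)

[thresholds]
theta_e = 21.25    # provenance: paper; basis: amount [CycE]*M, crossing up
theta_a = 12.5     # provenance: paper; basis: concentration [CycA], up
theta_b_hi = 80.0  # provenance: paper; basis: concentration [CycB], up
theta_b_lo = 3.0   # provenance: paper; basis: concentration [CycB], down

[states]
# Mean of the exponential waiting-time component per state, hours.
# lambda_1 = 2 h is a paper value; lambda_2 = 0 (no stochastic component out
# of state 2) and T_det for S phase = 7 h are paper statements; the remaining
# lambdas are calibrated.
lambdas = [2.0, 0.0, 0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
t_det_s = 7.0      # provenance: paper (DNA synthesis requires at least 7 h)

[growth]
gamma = 0.034657359027997264   # provenance: calibrated; ln 2 / 20 h
mode = "exponential"           # "exponential" | "linear"

[division]
delta_mean = 0.5     # provenance: paper
delta_sd = 0.0167    # provenance: paper
delta_clip_lo = 0.1  # provenance: calibrated (guard against Gaussian tails)
delta_clip_hi = 0.9  # provenance: calibrated

[noise]
threshold_sd = 0.033   # provenance: paper (Gaussian G, mean 1, sigma 3.3%)
dna_sd = 0.03          # provenance: paper
cyclin_sd = 0.15       # provenance: paper

[initial]
cyc_a = 1.0   # provenance: paper
cyc_b = 1.0   # provenance: paper
cyc_e = 1.0   # provenance: paper
mass = 3.0    # provenance: paper

[contact_inhibition]
p0 = 0.5        # provenance: paper (maximal G1a exit rate, 1/h)
n_half = 11000  # provenance: paper (N_0, inhibition midpoint, cells)
n_width = 500   # provenance: paper (N_1, transition width, cells)
n_init = 500    # provenance: paper (starting cells)
days = 10       # provenance: paper (duration of the experiment)
hard_cap = 200000  # provenance: calibrated (runaway-population guard)
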