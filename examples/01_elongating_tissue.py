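"""Simulate one elongating tissue and watch its shape coefficients.

Runs the one-cell-type filopodial-tension model at a desk-friendly
size (36 cells, 20,000 MCS) and prints the scaled 2- and 3-lobe
LOCO-EFA coefficients along the way.  L2/L1 measures elongation
(0 = circle); L3/L1 measures three-lobed complexity.  Expect L2/L1 to
climb from ~0.1 to well above 0.25 as convergent extension kicks in.
"""

import warnings

from gastrusim import SimConfig, Simulation

warnings.filterwarnings("ignore")

config = SimConfig(model="ce_one_type", n_cells=36, lambda_f=20.0,
                   j_cell_medium=20.0, seed=0)
sim = Simulation(config)
record = sim.run(20_000, record_every=2_000)

print(f"{'MCS':>7}  {'L2/L1':>6}  {'L3/L1':>6}")
for t, r2, r3 in zip(record.mcs, record.l2_over_l1, record.l3_over_l1):
    print(f"{t:>7}  {r2:>6.3f}  {r3:>6.3f}")

r2, r3 = record.final()
verdict = "elongated" if r2 > 0.25 else "still round"
print(f"\nfinal shape: L2/L1 = {r2:.3f}, L3/L1 = {r3:.3f} ({verdict})")
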