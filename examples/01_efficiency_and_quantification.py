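"""Standard-curve efficiency calibration and CP -> Ca conversion.

Simulates a 7-point 2-fold dilution series (5 ng down to 0.078 ng) for a
primer pair with true per-cycle amplification factor E = 1.95, estimates
E from the regression of CP on log2(input), and converts a few CP values
to log2-scale relative abundances (Ca = -CP * log2(E)).
"""

import coralstress as cs

series = cs.simulate_dilution_series(
    true_E=1.95, cp_at_max=16.0, n_points=7, fold_step=2.0,
    noise_sd=0.15, seed=7, gene_id="Hsp16",
)
print("dilution series (amount ng, CP):")
for amount, cp in series.points:
    print(f"  {amount:7.3f}  {cp:6.2f}")

est = cs.estimate_efficiency(series)
print(f"\nslope = {est.slope:.4f} cycles per log2(ng)")
print(f"E     = {est.efficiency:.4f}   (true 1.95; QC pass: {est.qc_pass})")
print(f"R^2   = {est.r_squared:.4f}")

for cp in (18.0, 25.0):
    ca = cs.cp_to_ca(cp, est.efficiency)
    print(f"CP {cp:5.1f} -> Ca {ca:8.3f}")
print("\nA lower CP means more template; one Ca unit is a 2-fold "
      "difference in starting amount.")
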