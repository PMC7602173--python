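"""Feasible (field, gradient) regions for membrane-crossing deadlines.

For each crossing deadline the steady-state force balance fixes the minimum
field-gradient product; the region of the device box above that hyperbola is
what the operator may use.  Shorter deadlines shrink the region.
"""

import nanoferry as nf
from nanoferry.config import carrier_from_config
from nanoferry.dynamics import Environment

model = nf.reference_model()
carrier = carrier_from_config()
env = Environment()

regions = nf.design_for_times((30.0, 60.0, 120.0, 300.0, 600.0), model, carrier, env)
print(f"{'t_cross':>8} {'v_s [m/s]':>11} {'product [T^2/m]':>16} {'area':>10} {'empty':>6}")
for r in regions:
    print(f"{r.meta['t_cross_s']:>7.0f}s {r.meta['v_s_m_per_s']:>11.3e} "
          f"{r.meta['nominal_product_T2_per_m']:>16.4e} {r.area():>10.4e} "
          f"{str(r.is_empty):>6}")

print("\ndevice capacity (corner product):",
      nf.feasible_region(0.0, 1.0).bz_max * nf.feasible_region(0.0, 1.0).grad_max,
      "T^2/m")

# The product column is mu0 H(1) v_s / (V chi): the field-gradient product
# whose magnetophoretic force balances the membrane's steady resistance at
# crossing speed v_s.  All five deadlines stay far below the 0.432 T^2/m
# capacity of a 2.4 T / 0.180 T/m device, so each region is non-empty and
# regions nest as the deadline relaxes.
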