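"""Reproduction number and final epidemic size of the constant-contacts model.

Builds the baseline disease parameters, reports R0 under both kernel
conventions, then runs the homogeneous constant-contacts epidemic and
compares its attack rate with the implicit final-size equation.
"""

import epibehave as eb
from epibehave.kernel import final_size

dp = eb.DiseaseParams()  # baseline: beta=0.01324, kappa=1/5, gamma=1/9, ...

r0_cont = eb.r0(dp, b=48.0, kernel="continuous")
r0_disc = eb.r0(dp, b=48.0, kernel="discrete")
print(f"R0 (continuous kernel): {r0_cont:.4f}")
print(f"R0 (discrete kernel):   {r0_disc:.4f}")
# The continuous value is the conventional ODE linearization (calibrated to
# 2.4); the discrete value is the one consistent with the daily update rule.

state0 = eb.EpidemicState(S1=1.0 - 1e-4, E1=1e-4)  # homogeneous population
res = eb.simulate_constant(state0, dp, b=48.0, horizon_days=3000)
z = final_size(r0_disc)
print(f"simulated attack rate:  {eb.attack_rate(res):.4f} ({res.days[-1]} days)")
print(f"implicit-equation root: {z:.4f}")
# With everyone at C* = 24 contacts/day the cumulative infected fraction
# matches the classic z = 1 - exp(-R0 z) prediction for the daily kernel.
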