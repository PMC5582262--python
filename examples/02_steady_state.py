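"""Steady-state 1,5-AG trajectories for normal and diabetic pregnancy.

At steady state the plasma volume cancels and the concentration is
C* = f(w)·k_i / (GFR_day(w)·(1 − r)); because 1 − r is tiny, the curve
is exquisitely sensitive to the reabsorption fraction.
"""

import numpy as np

import gestag as g

weeks = np.arange(6.0, 39.0, 4.0)

normal = g.KineticParams(k_i=5.0, glucose=5.0)
diabetic = g.KineticParams(k_i=5.0, glucose=8.9, reabs_form="stickle")

t_n = g.trajectory(weeks, normal)
t_d = g.trajectory(weeks, diabetic)

print("week   normal (ug/mL)   diabetic (ug/mL)")
for w, cn, cd in zip(weeks, t_n.concentration, t_d.concentration):
    print(f"{w:4.0f}   {cn:14.2f}   {cd:16.2f}")

print("\nBoth curves fall across gestation as GFR rises; the diabetic curve")
print("sits severalfold lower because glucose above 7.4 mM suppresses")
print("tubular reabsorption (r = 0.99486 at 8.9 mM vs 0.9984 normally).")

# closed form and ODE integration agree
w = 20.0
closed = g.steady_state_closed_form(w, normal)
integ = g.steady_state_by_integration(w, normal)
print(f"\nWeek {w:.0f} steady state: closed form {closed:.6f}, "
      f"ODE integration {integ:.6f} ug/mL")
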