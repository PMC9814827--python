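"""Classify a grid of initial states: no-growth, converging, diverging.

At the reference parameters (alpha=1, gamma=5, eta=5, rho=8) the stiffening
threshold is far above the reachable stress, so most growing starts blow up;
only starts whose rigidity rises fast enough converge, and starts below the
strain threshold with a rigidity target above their stress never grow.
"""

import seedshell as ss

params = ss.ModelParameters(alpha=1.0, gamma=5.0, eta=5.0, rho=8.0)
smap = ss.stream_map(params, p=1.0, r_range=(0.5, 2.5), k_range=(0.2, 3.0), n_grid=15)

print("start-state classes over the 15x15 grid:")
for label, count in sorted(smap.class_counts().items()):
    print(f"  {label:>10}: {count}")

fp = ss.solve_fixed_points(params)
print(f"steady-stress roots: {[round(x, 5) for x in fp.roots]}")
print(f"stiffening-mediated arrest possible: {fp.exists}")
print("pressure does not affect steady-state existence:",
      ss.predict_pressure_invariance(params, 0.5, 1.5))
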