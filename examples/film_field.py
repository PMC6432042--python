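"""Concentration inside the hydrolysing coating at successive times.

Inverts the film solution theta_f(eta, tau) on the thick-coating
condition (Dr = 0.1, Vr = 3, l = 2, k = 0.05/day).  The film fills from
the core side, then drains outward into the bath as release completes.
"""

import numpy as np

from crfrelease import film_concentration, scenario_by_name

sc = scenario_by_name("film-field")
eta = np.linspace(1.0, sc.params.l, 6)
tau = np.array([0.1, 0.3, 0.5, 0.9])
field = film_concentration(eta, tau, sc.params)

print("theta_f(eta, tau) in the coating, " + str(sc.params))
print(f"{'eta':>5}  " + "  ".join(f"tau={t:g}" for t in tau))
for i, e in enumerate(eta):
    print(f"{e:5.1f}  " + "  ".join(f"{v:7.4f}" for v in field.values[i]))
print("\nRows run from the core/film interface (eta=1) to the outer "
      "surface (eta=2); each column is one snapshot in time.")
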