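"""Closed-form hydrolysis limits of the polyester coating.

Two diffusion-free bounds for the coating chemistry: the reaction-dominant
monomer growth theta_r0*exp(k*t), and the maximum time to convert every
ester bond, t_max = (1/k)*ln(Mn0/M1).
"""

from crfrelease import reaction_limit, t_max

k_room = 0.015      # 1/day, aqueous hydrolysis near room temperature
k_hot = 0.081       # 1/day, literature rate at elevated temperature

print("reaction-dominant monomer fraction theta_r(t) = theta_r0*exp(k*t):")
for t in (0.0, 10.0, 30.0, 60.0):
    print(f"  t={t:5.0f} d  k={k_room}/d  theta_r = "
          f"{reaction_limit(t, k_room, 1.0):7.3f}")

print("\nfull ester-bond conversion bound t_max = ln(Mn0/M1)/k:")
for k in (k_room, k_hot):
    print(f"  k={k:5.3f}/d, Mn0/M1=1000  ->  t_max = "
          f"{t_max(k, 1000.0, 1.0):7.2f} days")
print("\nA slower rate stretches the degradation window linearly; the "
      "molecular-weight ratio enters only logarithmically.")
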