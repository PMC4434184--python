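"""Score nucleosome placements on a short sequence and print its occupancy.

Builds a 400-bp sequence with a stiff poly-dA:dT insert, computes the
forced-bending deformation energy at every dyad, the Boltzmann formation
potential, and the 51-bp-averaged occupancy, then prints the occupancy at
a few positions.  The dip over the poly-A block shows the model's
nucleosome-inhibitory reading of homopolymer runs.
"""

import numpy as np

from nucbend import EnergyModel, normalize_occupancy, occupancy_profile

rng = np.random.default_rng(7)
seq = (
    "".join(rng.choice(list("ACGT"), size=150))
    + "A" * 100
    + "".join(rng.choice(list("ACGT"), size=150))
)

model = EnergyModel()
pe = model.placement_energy(seq[100 - 64 : 100 + 65])
print(f"placement at dyad 100: torque F_b = {pe.F_b:.4f}, energy E = {pe.E_total:.2f}")

occ = occupancy_profile(seq, model=model)
norm = normalize_occupancy(occ, "auto")
for pos in (100, 200, 300):
    print(
        f"position {pos}: occupancy O = {occ.values[pos]:.3e}, "
        f"log-ratio vs mean = {norm.values[pos]:+.2f}"
    )
print(
    "The poly-A centre (position 200) carries the lowest occupancy: "
    "a rigid homopolymer run resists the imposed bend, raising the "
    "deformation energy and suppressing the Boltzmann weight."
)
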