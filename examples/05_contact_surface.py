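"""Solvent-accessible and contact surface area.

Computes SASA for a single probe-expanded sphere (against the closed
form), then the buried interface ½(S_A + S_B − S_AB) of the synthetic
motor-track complex in contact and pulled apart.
"""

import numpy as np

from kinfield import (
    GeneratorSpec,
    contact_surface_area,
    make_toy_complex,
    motor_selection,
    sasa,
    track_selection,
)

# single sphere: SASA = 4π(r + probe)²
res = sasa(np.zeros((1, 3)), radii=np.array([1.4]), probe=1.4, n_points=960)
exact = 4 * np.pi * 2.8**2
print(f"single sphere r=1.4 Å, probe 1.4 Å: {res.per_atom[0]:.2f} Ų "
      f"(closed form {exact:.2f} Ų)")

structure = make_toy_complex(GeneratorSpec())
motor, track = motor_selection(structure), track_selection(structure)
coords, radii = structure.coordinates, structure.radii

csa_contact = contact_surface_area(coords, radii, motor, track)
pulled = coords.copy()
pulled[motor.atom_indices, 0] += 25.0  # pull the motor 25 Å off the track
csa_pulled = contact_surface_area(pulled, radii, motor, track)

print(f"contact surface area, docked complex:  {csa_contact:.3f} nm²")
print(f"contact surface area, pulled apart:    {csa_pulled:.3f} nm²")
print()
print("The docked interface buries a finite area; separating the domains")
print("beyond probe reach sends the contact surface area to zero.")
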