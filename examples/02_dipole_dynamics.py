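"""Dipole-moment dynamics of a charged mobile domain under a field.

Simulates a short run of the synthetic motor-on-track complex with and
without a perpendicular (Y) field and compares the dipole azimuth: the
field pulls the dipole toward its own direction.
"""

import numpy as np

from kinfield import (
    FieldCondition,
    GeneratorSpec,
    dipole_series,
    make_toy_complex,
    motor_selection,
    simulate_trajectory,
    window_stats,
)

DURATION = 6_000.0  # ps — short demo run
WINDOW = (3_000.0, 6_000.0)

spec = GeneratorSpec(seed=7, duration=DURATION)
structure = make_toy_complex(spec)
motor = motor_selection(structure)

for label, evec in [("none", (0, 0, 0)), ("Y", (0, 100.0, 0))]:
    cond = FieldCondition(label, np.array(evec, dtype=float))
    traj = simulate_trajectory(
        structure, GeneratorSpec(seed=7, duration=DURATION, field=cond)
    )
    series = dipole_series(traj, motor)  # origin: per-frame center of mass
    stats = window_stats([series], WINDOW)
    print(
        f"{label:>4}: |p| = {stats.magnitude_mean:6.1f} ± {stats.magnitude_sd:4.1f} D, "
        f"azimuth = {stats.azimuth_mean:+6.2f} ± {stats.azimuth_sd:4.2f} deg "
        f"(n={stats.n_frames})"
    )

print()
print("The Y field shifts the mean azimuth (angle in the XY plane from +X")
print("toward +Y) upward relative to the no-field run: the dipole rotates")
print("toward the applied field.")
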