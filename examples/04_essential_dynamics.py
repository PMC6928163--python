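"""Essential dynamics: recovering planted collective modes.

Plants two orthogonal collective displacement patterns (variances 9 and
1 Ų) on a weak-noise trajectory, fits the positional covariance, and shows
that the leading eigenvalues and mode directions are recovered.
"""

import numpy as np

from kinfield import (
    GeneratorSpec,
    Selection,
    cluster_spread,
    fit_ed_model,
    make_toy_complex,
    plant_modes,
    project,
    simulate_trajectory,
)

# weak thermal background, densely sampled so the planted variances
# dominate the spectrum and their estimates converge
spec = GeneratorSpec(seed=3, duration=10_000.0, stride=5.0, temperature=10.0)
structure = make_toy_complex(spec)
traj = simulate_trajectory(structure, spec)

sel = Selection.all(structure)
k3 = 3 * structure.n_atoms
rng = np.random.default_rng(8)
Q, _ = np.linalg.qr(rng.normal(size=(k3, 2)))
planted = plant_modes(traj, [(Q[:, 0], 9.0), (Q[:, 1], 1.0)], seed=12)

model = fit_ed_model(planted, sel)
print("leading eigenvalues (Ų):", np.round(model.eigenvalues[:4], 3))
for k in range(2):
    cos = abs(float(model.eigenvectors[:, k] @ Q[:, k]))
    print(f"mode {k + 1}: planted variance {[9.0, 1.0][k]}, "
          f"recovered {model.eigenvalues[k]:.2f}, |cos(angle)| = {cos:.4f}")

proj = project(planted, model, k=2)
print(f"first-two-mode cluster spread: {cluster_spread(proj):.2f} Ų")
print()
print("The two planted variances dominate the spectrum, the recovered")
print("eigenvectors are essentially parallel to the planted directions, and")
print("the spread equals (to sampling error) the sum of the eigenvalues.")
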