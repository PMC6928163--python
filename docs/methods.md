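# Methods

`kinfield` analyses molecular-dynamics trajectories of a charged protein
domain docked on a restrained partner under an external uniform electric
field. This note records the models, conventions, numerical choices, and
the limits of what the synthetic test bed can show.

## Canonical data model and units

Everything runs through four in-memory types (`Structure`, `Trajectory`,
`Selection`, plus per-atom `Atom` records). Coordinates are ångström
internally everywhere; GRO nanometres are converted on read. Times are
picoseconds, charges elementary charges (e), dipoles debye, fields MV/m,
energies J and kT, areas Ų per atom and nm² per total. Atom indices are
0-based internally; residue numbers stay as authored in the source file so
reports match published residue labels. Time windows are half-open
`[t0, t1)` ps ("last 5 ns of a 30 ns run" = `[25000, 30000)`); the
contact-surface-area *block* statistics use end-anchored `(t0, t1]` blocks
so that frames written at stride multiples s, 2s, …, T fill each block
exactly (250 frames per 5-ns block at a 20 ps stride).

Missing charges or radii default to zero with a logged warning rather than
an error, so purely geometric analyses run on bare coordinate files;
charge- or radius-dependent stages of the pipeline skip themselves loudly
when everything is zero.

PDB/GRO/DCD/XTC parsing and writing is delegated to MDAnalysis. Two
formats are owned by this package: a plain-text trajectory fallback (`t
<ps>` line, then one `x y z` line per atom) and whitespace-delimited
per-atom value tables keyed by `(residue_name, atom_name)` with `*` as a
residue wildcard. The binary trajectory dialects store a stride but no
absolute time origin; round trips preserve coordinates and stride, and
`read_trajectory(dt=, t0=)` re-bases the clock. Joining replicate runs
re-bases times to stay strictly increasing and keeps a provenance map
`(replicate, original frame, original time)` per output frame.

## Superposition and displacement

Frames are superimposed by the Kabsch algorithm (SVD of the cross-
covariance with the determinant correction, so reflections are never
returned) on a caller-chosen subset of low-fluctuation atoms with uniform
weights. Degenerate fits (fewer than 3 points, collinear points) raise
rather than returning an arbitrary in-plane rotation. Each frame gets its
own fit on the subset; the fitted transform is applied to all atoms.

The displacement statistic compares one coordinate component of each
selected atom against a reference structure built as the per-atom mean
over the pooled, aligned no-field replicates (e.g. 3 × 1,500 = 4,500
frames), never per replicate. Mean and SD are taken over all window frames
pooled across replicates; the SD is the population form (divisor n),
a descriptive spread over frames, and no attempt is made to separate
replicate-to-replicate variance from frame scatter.

## RMSF

For residue n over M aligned window frames,
RMSF_n = sqrt((1/M) Σ_m |r_nm − ⟨r_n⟩|²), with ⟨r_n⟩ the within-window
mean and divisor M (population form). Replicates are pooled by windowing
each run on its own clock, concatenating, and evaluating the sum over the
pooled frame set. The default window is `[10000, 30000)` ps, i.e. the
production segment after equilibration of a 30-ns run. A heuristic warning
fires when the fit subset itself moves more than 3 Å RMS about its mean —
the signature of a trajectory that was never superimposed.

## Essential dynamics

The 3N×3N positional covariance C_ij = (1/M) Σ_t (x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)
of the selected atoms is decomposed as C = T Λ Tᵀ with `numpy.linalg.eigh`
(dense; 3N is a few hundred at most in the intended use, so no truncated
solver). Determinism choices: eigenvalues sorted descending; each
eigenvector's largest-magnitude component is made positive; among exactly
equal eigenvalues the sign-fixed eigenvectors are ordered
lexicographically. Projections multiply mean-centered frame vectors into
the first k eigenvectors; on the training set the per-mode projection
variance reproduces the eigenvalue (tested as a spectral identity). The
scalar "cluster spread" of a projection cloud is the trace of its 2×2
covariance over the first two modes. The deselection of high-fluctuation
residues before the fit is the caller's decision — a helper flags residues
above an RMSF quantile but is not applied automatically. Models serialise
to a single JSON file (arrays as lists): the matrices are small and a
text-only artifact is worth more than a compact one here.

## Surface areas

SASA uses Shrake–Rupley-style sphere-point sampling with a deterministic
golden-spiral point set (no RNG; bit-reproducible at fixed point count,
default 960, floor 32). A point on atom i's probe-expanded sphere
(radius rᵢ + probe, probe default 1.4 Å = 0.14 nm water) is accessible if
strictly outside every other expanded sphere. Exactly coincident spheres
(identical center and radius) are treated as duplicates — only the first
copy carries area — so the union of a structure with a coincident copy
counts its surface once, which is what the contact-area formula requires
in its degenerate limit. Candidate neighbours come from a KD-tree query
whose results are contractually identical to the all-pairs loop (tested
bit-for-bit). Contact surface area between disjoint selections is
CSA = ½(S_A + S_B − S_AB), all three terms with the same probe and point
set. Atomic radii are an input: absolute SASA/CSA values depend on the
radii table supplied, and no specific force-field radii set is bundled.

## Field energetics

Linear force F = q·E (1 e · 1 MV/m = 0.160218 pN) and dipole coupling
U = p·E (debye → C·m via 1 D = 3.33564×10⁻³⁰ C·m), reported in J and in
kT at a stated temperature (default 296 K). All conversion literals are
pinned to CODATA-2018 in one module (`kinfield.constants`); a worked
consequence used throughout the tests: a 1,150 D dipole parallel to a
100 MV/m field couples at 93.9 kT at 296 K, and a −5 e net charge in the
same field feels 80.1 pN.

## The synthetic generator

The generator emulates the *statistical* structure of a docked
motor-on-track MD study, not its microphysics. Geometry: the track is a
3-row lattice patch in the YZ plane (long axis Y, 3.8 Å spacing) —
deliberately non-collinear so a least-squares fit on track atoms pins all
rotational degrees of freedom; the motor is a 24-residue golden-spiral
shell of radius 6 Å centered at +10 Å on X, i.e. docked in +X contact,
one pseudo-atom per residue (treated as Cα by the analyses). Motor
charges are ±1 e assigned by each atom's projection onto an in-plane
direction ≈20° from +X, with enough extra −1 e sites to reach the
configured net charge (−5 e by default), giving a resting dipole of a few
hundred debye pointing near +X with a small +Y component.

Dynamics: overdamped Langevin (Euler–Maruyama),
dx = (F_el + F_restraint + qE)/γ·dt + √(2k_BT/γ)·dW, on an elastic
network connecting all pairs within 10 Å of the initial geometry at their
native distances (k = 1 kcal mol⁻¹ Å⁻²); track atoms are additionally
tethered to their initial positions with the same 1 kcal mol⁻¹ Å⁻²
restraint. Study-design defaults mirror the emulated experiment: five
field conditions {none, X, −X, Y, −Y} at 100 MV/m, three replicates each,
30 ns per run written every 20 ps (1,500 frames; 4,500 joined no-field
frames; 250 frames per 5-ns window). Friction (50 kcal mol⁻¹ ps Å⁻²),
timestep (0.5 ps) and temperature (300 K) were chosen once so that (a)
per-coordinate fluctuations land at a realistic Cα scale (~0.2–0.8 Å
RMSF), (b) relaxation times are a few ps, so runs equilibrate within the
first percent of frames and 20-ps-strided frames are nearly independent,
and (c) a full 15-run study integrates in about a minute on one core.
These are desk-scale modelling choices, not claims about physical friction.
A step moving any atom more than 10 Å raises a stability error instead of
silently producing garbage.

Seeding: a run is bit-reproducible from its spec; the study layout derives
per-run seeds from the master seed by a splitmix64 chain over the
condition label's bytes and the replicate number (documented because any
re-implementation must match it to reproduce fixtures). The noise stream
depends only on the seed — not on the field — so two runs with the same
seed under different fields are paired samples differing only by the
deterministic field forces.

What the generator does *not* emulate: solvent and hydrodynamics,
anharmonicity and side-chain chemistry, polarizability (charges are fixed,
so the field can displace and reorient charged residues but not induce
electronic polarization), periodic boundary conditions, and the absolute
magnitudes of any published observable. Passing tests therefore demonstrate
that the analysis stack recovers planted or mechanically forced signals of
realistic size and sign — not that it reproduces any particular protein's
numbers.

## Pipeline

The pipeline aligns every run to the initial structure on the track
subset, builds the pooled no-field average structure, re-aligns everything
to it, and then executes the stages: dipole series and circular-mean
window statistics per condition; pooled RMSF; per-residue displacement of
field conditions against the reference (x component for ±X fields, y for
±Y); essential-dynamics fit on the joined no-field trajectory with
projections and cluster spread per condition; contact-surface-area series
with block statistics (frames subsampled for this stage by a configurable
stride, default every 5th frame, because sphere-point SASA over every
frame of 15 runs dominates runtime without changing block means
materially); and the energetics report per condition using the
within-window mean dipole magnitude. Azimuth statistics use the circular
(vector) mean with the SD of wrapped deviations, degenerating to the
arithmetic mean for narrow angle ranges. The dipole origin defaults to the
selection's per-frame center of mass and is explicit and logged because a
net-charged selection has an origin-dependent dipole.

Stage failures write a `<stage>.FAILED` marker with the traceback and do
not abort the rest; a manifest records version, config hash, seed and
outputs. Fixed config + seed gives byte-identical outputs (tested by
hashing). Numeric CSVs carry full float precision.

## Known limitations

* The azimuth convention (signed angle in the XY plane from +X toward +Y,
  range (−180°, 180°]) is a documented choice; other conventions differ by
  sign or offset.
* Absolute SASA/CSA values depend on the caller's radii table; only
  relative comparisons between conditions are radii-robust.
* The displacement SD pools frames across replicates and does not report
  between-replicate variance separately.
* The generator's coarse one-bead-per-residue elastic network cannot
  produce secondary-structure-specific effects; per-residue findings on
  real trajectories need real force-field runs.
* No PBC unwrapping: trajectories are assumed whole-molecule and
  pre-wrapped.
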