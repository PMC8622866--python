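# Methods

This note documents the models, defaults and numerical choices behind
`zincagg`, and what the synthetic-data generator does and does not
emulate.

## Units, systems, counting conventions

Coordinates are nanometres, times picoseconds, boxes cubic and
periodic; all distances use the minimum-image convention (rejected when
a cutoff reaches half the box edge, where the convention becomes
ambiguous).  The *molecule unit* is the counting basis of every
aggregation statistic: an Aβ16 monomer (with or without a zinc in its
coordination centre), a zinc-bridged dimer — two peptide chains sharing
one zinc, counted as **one** molecule — or a free zinc ion, which is
never counted as a molecule.  The six bundled presets reproduce the
study conditions: 15 nm box, species counts (e.g. 19 dimers; 20
zinc-free monomers; 1 dimer + 19 zinc-saturated monomers), minimum
initial separations of 2.4/2.7/3.1/4.1 nm, durations of 100–200 ns.

## Complex detection

Units u, v are in contact iff min over atom pairs of the minimum-image
distance is ≤ the contact cutoff.  The cutoff is a free parameter with
no canonical value for pseudo-atom systems; the default is **0.45 nm**
(heavy-atom contact range) and every pipeline stage echoes it to its
log.  Neighbour search uses a periodic k-d tree
(`scipy.spatial.cKDTree` with `boxsize`), which is exact, and the test
suite checks it against an all-pairs brute-force scan.  Complexes are
connected components (networkx).  The *proximity merge* joins
complexes whose minimum inter-complex atom distance is ≤ the merge
cutoff, transitively; the default **1.0 nm** operationalises the
convention that conglomerates "very close" to each other count as one
complex, and equals the identity when set to the contact cutoff.

## Connectivity length

L_c = Σᵢ √Nᵢ is computed at full precision and rounded half-even to two
decimals only for display.  Bounds √M ≤ L_c ≤ M and the strict merge
inequality √(a+b) < √a + √b are covered by property tests.  L_c is not
normalised: values are comparable only at equal total unit count (the
9-dimer preset's 5.65 cannot be compared with the 19-unit systems).

## Zinc coordination

Donor atoms are the His imidazole nitrogens (ND1/NE2), Asp/Glu
carboxylate oxygens (OD1/OD2/OE1/OE2) and the backbone N of residue 1
(the free N-terminal amine).  Backbone carbonyls and waters are
excluded: every coordinating group reported for this system is in the
whitelist.  The coordination cutoff default is **0.30 nm** — typical
Zn–N/O bonds are 0.20–0.23 nm plus thermal margin — and is attached to
every shell.  Motif rules:

- *dimer_bridge*: contacts span ≥ 2 chains; each chain's contact
  residues ⊆ {Glu11, His13, His14, Asp1}; an acidic partner (Glu11 or
  Asp1) and His14 each present somewhere.  This accepts the observed
  variants (Asp1 substituting a glutamate; an extra His13 bond) without
  admitting arbitrary chemistry.
- *monomer_closed*: single chain, His6 plus ≥ 2 of
  {Glu11, His13, His14} — the closed site of the zinc-saturated
  monomer, which aggregates poorly.
- otherwise *other*; empty shells are *unbound*.

Capture events over a trajectory use the distance from the ion to the
donor-site centroid: an event opens at the first frame of a run of
≥ `min_persistence` frames (default **10**, suppressing single-frame
dips) within the capture cutoff; runs are disjoint by construction.

## Conformational analysis

Kabsch superposition uses the SVD solution with the determinant
correction, so reflections are excluded and chirality preserved;
collinear or < 3-point inputs raise a degeneracy error.  φ/ψ follow the
IUPAC sign convention in (−180°, 180°], computed with the standard
two-plane arctan2 formula; chain termini have undefined φ/ψ and
residues with incomplete N/CA/C backbones are skipped with a warning
(the simulator's one-pseudo-atom-per-residue scaffolds therefore yield
none — full-backbone fixtures are used for dihedral work).  Where a
per-frame scalar is needed from many residue dihedrals (a φ/ψ
landscape), the reduction is the circular mean; it is a configurable
choice, not a canon.

Nearest-neighbour clustering peels iteratively: take the member with
the most neighbours within the RMSD threshold (ties to the lowest
index), emit it with its neighbours, remove, repeat while anyone has a
neighbour.  The greedy first pick attains the maximum possible cluster
size, which the tests confirm against exhaustive enumeration of peeling
orders.

Free-energy surfaces are 2D histograms, F/kT = −ln(n/n_max), so the
most occupied bin is exactly 0 and empty bins are masked rather than
zero-filled.  Default **32×32** bins spanning the data with 5% padding
per side (the appropriate resolution depends on sample count; 32² is a
reasonable default for 10³–10⁵ samples).  Local minima are occupied
bins not exceeded by any occupied 8-neighbour; an optional watershed
pass estimates each minimum's saddle and discards basins shallower than
`depth`, and `min_count` raises the occupancy floor to suppress
single-sample minima in sparse tails.  Representatives are the frames
nearest a minimum bin's centre; minima membership across two landscapes
intersects as frame-index sets.

## The Brownian aggregation simulator

The generator emulates the statistical structure of the study systems,
not their physics.  Each unit is a rigid scaffold — one pseudo-atom per
residue (Asp1…Lys16) per chain on a compact helix of radius 0.35 nm,
two offset chains for a dimer, a single atom for an ion.  Dimers and
zinc-saturated monomers carry no explicit zinc atom: zinc occupancy is
encoded in the species label and its binding propensity, while explicit
ions appear as `zinc_ion` units and in the coordination fixtures.

Dynamics: per step each cluster takes an independent Gaussian
displacement of per-axis variance 2·D·Δt (overdamped Brownian motion;
verified to 5% in the tests).  Defaults: Δt = **100 ps**, D =
**1.5×10⁻⁴ nm²/ps** for monomers (a small-peptide aqueous value),
1.0×10⁻⁴ for the bulkier dimer, 7×10⁻⁴ for the bare ion; cluster
diffusion scales as size^(−1/3) (Stokes-like — the study is silent on
conglomerate kinetics).  When units of different clusters come within
the contact radius (**1.8 nm**, the mean dimer diameter scale) they
bind with a per-step species-pair probability, the smaller cluster
snapping to the 0.5 nm bonded spacing so that geometric contact
detection sees every bond.  Binding is **irreversible**, reflecting the
observation that zinc-mediated bridges never broke on the simulated
timescale; consequently bound-pair sets grow monotonically and, with
certain binding, the largest detected complex never shrinks.

Binding probabilities are deliberately small (dimer–dimer 0.05 down to
0.003 for zinc-saturated pairs, 0 for anything involving a free ion,
which never joined conglomerates in the study): a pair dwells of order
(contact radius / step length)² ≈ 30–40 steps per encounter, so only
p·dwell ≲ 1 keeps aggregation *reaction-controlled*.  In the
diffusion-limited regime every encounter sticks and species propensity
— the feature the generator exists to encode, with the ordering dimer >
zinc-free monomer > zinc-saturated monomer — would have no effect.
With these defaults the three propensity presets reproduce the
qualitative ordering of final connectivity lengths over seeds
(dimer-seeded < zinc-free < zinc-saturated); the numeric values are not
comparable to the atomistic results.

What the generator does **not** emulate: intra-unit flexibility,
binding reversibility and rearrangement within clusters, explicit
solvent and electrostatics, zinc exchange between sites, and atomistic
packing.  Tests passing on synthetic data therefore demonstrate the
correctness of the *analysis* (detection, statistics, classification,
landscapes) under controlled conditions, not the fidelity of any
particular molecular force field.  Likewise, the atomistic-scale
results (the 5.54 Å ensemble RMSD, the 9-of-28 dominant cluster, zinc
return within 100 ns, the replica-exchange landscape structures) are
trajectory-dependent and are out of scope here; the corresponding
algorithms are validated by construction and by oracle tests instead.

## Problem sizes and reproducibility

Simulations used in tests and examples run 19–20 units for 10³ steps
(100 ns of model time) — the study scale — with ensembles of 20 seeds
for stochastic ordering checks; oracle suites use ≥ 100 randomised
systems of up to 60 units.  All randomness flows through
`numpy.random.default_rng` seeds carried in `SimParams`; identical
parameters give bit-identical trajectories, and the xyzb trajectory
format round-trips coordinates bit-exactly (PDB and GRO round-trip to
their 3-decimal column precision, 5×10⁻⁴ nm).

## File-format notes

PDB reading takes the first MODEL by default (the relevant experimental
structures are NMR ensembles; the model index is selectable) and maps
chains to units through an explicit chain→unit map, since a PDB cannot
express that two chains form one zinc-bridged dimer unit; the default
is one monomer unit per chain, and ZN HETATM records always become
`zinc_ion` units.  Coordinates are stored as read (unwrapped); wrapping
is applied at analysis time.  The internal `xyzb` dialect (header
`natoms time box_edge`, then `atom_id x y z` per atom) exists because
standard XYZ has no box record, which periodic analysis requires.
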