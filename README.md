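# zincagg

Analysis tools for zinc-induced aggregation of the amyloid-beta
N-terminal domain Aβ16 (residues Asp1…Lys16), the zinc-binding part of
the Alzheimer's-related Aβ peptides.  Zinc bridges two Aβ16 chains
through the ¹¹EVHH¹⁴ metal-binding segment (Glu11 and His14 of each
chain), and such dimers act as nuclei for the growth of non-fibrillar
aggregates.  The package is for people who study this process in
particle simulations: it detects molecular complexes in periodic-box
trajectories, quantifies aggregation, classifies zinc coordination
motifs, and builds free-energy landscapes — plus a coarse-grained
Brownian simulator to generate aggregating test systems.

## What it computes

**Complex detection.**  Two molecule units are in contact when any atom
of one lies within a cutoff (default 0.45 nm) of any atom of the other
under the minimum-image convention in a cubic periodic box; complexes
are connected components of this contact graph.  Conglomerates sitting
within a proximity cutoff (default 1.0 nm) can be merged into one
complex.  A *unit* is an Aβ16 monomer, a zinc-bridged dimer (counted as
**one** molecule), or a free zinc ion; zinc ions are never counted as
molecules.

**Connectivity length.**  Aggregation strength is scored with

    L_c = Σᵢ √Nᵢ

over the complexes i of a frame, Nᵢ the number of units in complex i.
For M total units, L_c ranges from √M (everything in one complex) to M
(all free): the smaller the connectivity length, the stronger the
aggregation.  It is not normalised across different M.

**Zinc coordination.**  Coordination shells are the donor atoms
(His ND1/NE2, Asp OD1/OD2, Glu OE1/OE2, the N-terminal amine) within a
cutoff (default 0.30 nm) of a zinc ion.  Shells are classified as the
two-chain *dimer bridge* (Glu11/His14 of both chains, with Asp1 and
His13 variants accepted), the single-chain *closed monomer* site
(His6 plus ≥ 2 of Glu11/His13/His14), *other*, or *unbound*; capture
events of an ion by a site are detected over a trajectory with a
persistence filter.

**Conformational analysis.**  Kabsch superposition RMSD
(reflection-free), radius of gyration, backbone φ/ψ dihedrals, pairwise
RMSD matrices, nearest-neighbour (peeling) cluster analysis, and
free-energy surfaces F/kT = −ln(n/n_max) over reaction-coordinate pairs
with local-minimum and representative-frame extraction.

**Synthetic systems.**  `build_system`/`simulate` place units in the
15 nm box at the study's minimum separations (2.4–4.1 nm) and run
overdamped Brownian dynamics with irreversible, species-dependent
sticky binding, ordered dimer > zinc-free monomer > zinc-saturated
monomer.  See `docs/methods.md` for the model and its limits.

## Worked example

```bash
python examples/connectivity_length.py
```

prints the six study systems' published end-state compositions and
their connectivity lengths:

```
system      t/ns  composition              L_c
system1      100  6+4+3+3+1+1+1+1        11.91
system2      100  11+8                    6.15
system2      200  19                      4.36
system3      100  10+2+2+2+2+1+1         10.82
system4      100  5+2+1+1                 5.65
system5      100  17+1+1                  6.12

Proximity merge (system2, 100 ns): (8, 7, 2, 2) -> (11, 8), L_c 8.3 -> 6.15
```

Reading: the dimer-seeded system 2 reaches L_c = 6.15 by 100 ns and a
single 19-unit complex (4.36) by 200 ns, whereas the zinc-saturated
monomer system 1 stalls at 11.91 — dimers, not zinc-loaded monomers,
drive aggregation.  The other examples (`simulate_aggregation.py`,
`zinc_coordination.py`, `free_energy_landscape.py`,
`cluster_ensemble.py`) each run one capability end to end and print
what the numbers mean.

There is also a thin CLI over the same functions:

```bash
zincagg run --preset system2 --seed 7 --out-dir out/
zincagg table2-check
```

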