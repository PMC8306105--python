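# Methods

This note documents the model behind `cgdock`, the parameters that matter,
the numerical choices, and what the synthetic test systems do and do not
demonstrate.

## Reduced representation

A protein chain is a sequence of Cα beads on a cubic lattice of spacing
0.61 Å. Consecutive beads must differ by one of the **allowed bond
vectors**: all integer triples whose length, scaled by the spacing, lies in
[3.5, 4.1] Å. This set contains 558 vectors, is closed under sign flips and
axis permutations (so 90° lattice rotations are exact symmetries), and lets
the virtual Cα–Cα bond fluctuate around its physical 3.8 Å while keeping
the move set local and enumerable. The spacing and band are implementation
choices: fine enough that projecting a real Cα trace onto the lattice costs
≲ 0.4 Å RMSD (the projector guarantees ≤ 0.6 Å for well-formed chains), and
coarse enough that the candidate sets per move stay small.

Projection is greedy: bead 0 rounds to the nearest node, each later bead
picks the allowed bond vector minimising the distance to its own target
position (lexicographic tie-break, occupied nodes skipped). Because each
bead aims at its absolute target, error does not accumulate; the procedure
is idempotent, and a chain already on the lattice is a fixed point.

Three pseudo-atom classes are rebuilt from the trace:

* **pb** — midpoint of each Cα–Cα bond, used to locate main-chain hydrogen
  bonds;
* **cb** — Cβ, placed 1.53 Å from Cα along the local frame direction
  `normalize(bisector + 0.57·normal)`, where bisector and normal come from
  the two bonds flanking the residue (terminal residues borrow the nearest
  interior bond pair, so every position is still a function of three
  consecutive Cα and the residue type);
* **sc** — united side-chain centre, along the same direction at a
  residue-type-specific distance (packaged table, 0 Å for Gly so sc ≡ Cα,
  1.53 Å for Ala so sc ≡ Cβ, up to ~4 Å for Arg/Trp). The table is an
  idealised-geometry simplification of database-derived side-chain
  centroids.

For perfectly collinear local backbones the frame is undefined and cb/sc
collapse onto Cα; the fixture generators avoid collinear chains except for
the deliberately degenerate "extended" template.

## Energy model

All terms are dimensionless (kT). The total is
`local + hbond + contact + restraint`:

* **Local bias** (−0.5 per 4-mer): rewards |Cα pseudo-dihedral| in the
  helix-like window 30–90° or above 150° (extended). Applying the window to
  the magnitude treats both chiralities alike — a deliberate
  coarse-potential simplification.
* **Hydrogen bonds** (−1.0 each): two peptide-bond centres at 4.2–5.5 Å
  whose bond vectors align to |cos| ≥ 0.5, at pb-index separation ≥ 3
  within a chain (any separation between chains). In an ideal α-helix this
  fires for (i, i+3) pairs, so helices score below extended chains.
* **Side-chain contacts**: a symmetric 20×20 matrix evaluated for sc pairs
  between hard core (3.0 Å) and cutoff (6.0 Å); pairs inside the hard core
  pay +3.0 each (a bounded soft core, so no term can diverge). Intra-chain
  pairs need sequence separation ≥ 3. The matrix is
  `e(a,b) = −1.2·h(a)·h(b)` with h the Kyte–Doolittle hydropathy rescaled
  to [0, 1]: hydrophobic pairs reach about −1 kT, polar pairs about 0. This
  is a self-contained stand-in for survey-derived contact statistics that
  preserves the class's driving force (hydrophobic association).
* **Restraints**: flat-bottom, two-tier. From the *input* coordinates,
  every pair with sequence separation ≥ 5 and Cα–Cα distance in 5–15 Å is
  restrained to its observed distance d0 with tolerance 1 Å and weight
  1 kT/Å; the penalty is `w·max(|d − d0| − 1, 0)` — linear, so large
  ligand excursions stay finite and recoverable. The receptor set has
  weight scale 1.0, the ligand set 0.1. The linear form (rather than
  quadratic) is a design choice favouring robustness to the large-scale
  ligand motion the method is built for.

The receptor weight (1 kT/Å) was calibrated so that a restrained globular
60-mer simulated at the coldest default temperature fluctuates at the
~1 Å RMSF scale (`scripts/acceptance.py` recomputes this; typical values
are 0.6–0.7 Å). Ligand fluctuation under the tenfold weaker tier is left
emergent, not capped.

## Sampling

Movers (default mixture in parentheses) all stay on-lattice and draw
uniformly from candidate sets that are functions of the *fixed*
surroundings, so forward and reverse proposals are equally likely and plain
Metropolis acceptance `min(1, exp(−ΔE/T))` is correct:

* single-bead re-draw (0.50): uniform over nodes compatible with both
  flanking bonds (the current position included);
* two-bead re-draw (0.15): uniform over all valid (v1, v2) bond pairs for
  the fixed end-to-end vector, sampled without materialising the set via a
  precomputed pair-count table (the allowed-set indicator convolved with
  itself);
* chain-end re-draw (0.10);
* fragment slide (0.10): ±1 lattice unit for a random 2–8 residue
  fragment, valid only if the boundary bonds survive;
* whole-ligand translation (0.075) and 90°/180°/270° lattice rotation about
  a random ligand bead (0.075) — the inter-molecular search moves.

Proposals that would break a bond, exceed the lattice band, or place two
beads on one node are auto-rejected. Excluded volume is therefore an
invariant of every sampled state, at both intra- and inter-chain level.

**Replica exchange.** The temperature ladder has geometrically growing
increments: increment k is `d0·r^k` with d0 solved so the hottest rung hits
t_max exactly (r = 1 recovers uniform spacing). Defaults: 20 rungs, t_min
1.0, t_max 2.5, r 1.15 — chosen so the coldest rung freezes the toy native
pose while the hottest lets the weakly restrained ligand partially unfold.
Adjacent rungs attempt swaps every 250 move attempts with probability
`min(1, exp((β_i − β_j)(E_i − E_j)))`; only temperature assignments are
exchanged. **Annealing** multiplies the whole ladder by 0.96 after each of
the 20 stages (the ladder cools as a whole; rung spacing shrinks
proportionally).

Energies are tracked incrementally — each move re-evaluates only terms
touching the moved beads (side-chain dependencies extend one residue each
way, plus the borrowed terminal frames). The cache is compared against a
full recomputation at every stage boundary; divergence beyond
1e-6·(1 + |E|) is a hard error, and the cache is re-synchronised there to
absorb benign float drift.

Each replica owns an independent Philox (counter-based) stream spawned from
the master seed, and exchange decisions use one more; runs are
bit-reproducible.

**Snapshots.** One "generated model" is counted per attempted move; every
50th is saved, i.e. exactly the 2% fraction — 500 snapshots per replica,
10,000 pooled models at the 20-replica default. The unit of "generated
model" is a convention of this implementation.

## Protocol

Inputs are PDB Cα traces (Biopython reader; residues ordered by resSeq +
insertion code; HETATM/waters/altloc B+ ignored; a standard residue without
Cα is a chain-gap error). The smaller protein should be the ligand — a
warning, not an error — and fully flexible ligands above 150 residues are
warned about as impractical. Starting poses place the ligand centre at a
uniformly random direction, radially adjusted (bisection) until its
distance to the nearest receptor Cα/sc atom is the configured offset
(default 20 Å, tolerance ±2 Å), with uniformly random orientation and
lattice-level clash rejection.

## Model selection

Contact maps use the 6 Å side-chain-centre criterion (inclusive). The 1000
models with most receptor–ligand contacts survive (ties broken by lower
energy, then model id — every tie-break in the pipeline is deterministic,
and maps are canonically ordered by model id before clustering, so results
are input-order invariant). Complete-link clustering (scipy linkage) under
the Jaccard distance `1 − |A∩B|/|A∪B|` (two empty maps: distance 0 by
convention) is cut at 30 clusters by default — the dendrogram has no
natural stopping rule in a density-ranking scheme, so the count is exposed
as a flag. Density is `members / mean pairwise distance`; singletons get
density 0 and rank last (convention). The representative minimises the
summed Jaccard distance to co-members. The ten densest clusters are
reported.

## Metrics

Superpositions are least-squares over proper rotations only (scipy
`align_vectors`); mirror images keep a residual. iRMSD superposes the
interface Cα of both molecules jointly (interface = residues with any
cross-interface sc distance ≤ 6 Å in the reference — the same criterion as
fNAT, for consistency). LRMSD superposes receptors only and reads the
ligand RMSD without further fitting. LoRMSD superposes ligand onto ligand.
RMSF uses the mean structure after per-frame superposition as the
reference (two fit-average refinement rounds), since "reference position"
is otherwise underdetermined. fNAT is the fraction of reference contacts
present in the model.

## Synthetic test systems

The fixture generator builds ideal-geometry toys: α-helices (rise 1.5
Å/residue, 100°/residue, radius 2.28 Å → 3.8 Å bonds), β-hairpins with a
0.5 Å zigzag (so side-chain frames are defined), straight extended chains,
and a compact three-helix bundle whose inter-helix distances populate the
5–15 Å restraint window like a real globular domain. Toy complexes pack a
ligand against a receptor at the closest clash-free separation with the
largest side-chain contact interface; "unbound-like" inputs apply random
hinge rotations (which preserve every bond exactly) scaled by bisection to
a requested superposed RMSD. Decoy ensembles perturb the ligand pose
rigidly with known labels, including an exact-native and a reversed-face
(fNAT = 0) member.

What these toys do **not** emulate: real side-chain packing statistics,
sequence-specific secondary-structure propensities, solvent effects beyond
the implicit contact term, multi-chain partners, and the size and
ruggedness of real binding-energy landscapes. Passing tests demonstrate
the correctness of the machinery (sampling, accounting, clustering,
metrics) and the calibrated fluctuation regimes — not docking accuracy on
real complexes.

## Problem sizes and defaults used in validation

The validation suite runs the full default accounting (20 replicas × 500
snapshots = 10,000 models) on a 30+12-residue toy complex, the restraint
calibration on a 60-residue bundle (20,000 move attempts at the coldest
rung), and the end-to-end smoke with 4 replicas × 50 snapshots plus an
injected near-native decoy ensemble. These sizes were chosen as the
smallest systems that exercise every contract of the pipeline.

## Known limitations

* The contact matrix is hydrophobicity-rank only; it has no electrostatics,
  no residue-pair specificity beyond the hydropathy product, and no
  orientation dependence.
* Ligand conformational cost grows quickly with chain length (every
  rotation/translation is composed of local moves), so large flexible
  ligands sample poorly.
* Cluster density ranking degenerates when many identical (e.g. empty)
  contact maps survive filtering; the filter's contact-count criterion is
  what protects against this, so very small pools should be filtered with
  proportionally smaller `keep`.
* No all-atom reconstruction: outputs are Cα traces with pseudo-atoms.
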