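# cgdock

Coarse-grained protein–protein docking with large-scale backbone
flexibility.

Most docking tools hold the protein backbones (almost) rigid and search
only the six rigid-body degrees of freedom. `cgdock` implements the
opposite regime for structural biologists who suspect their complex forms
with substantial conformational change: one binding partner (the
"receptor") fluctuates gently around its input structure while the other
(the "ligand") rotates, translates and *refolds* around it during a single
docking simulation — no separate flexibility stage.

This is feasible at desk scale because the model is drastically reduced:

* **Representation.** Each chain is a Cα trace restricted to a fine cubic
  lattice (0.61 Å spacing; 558 allowed bond vectors spanning Cα–Cα
  distances of 3.5–4.1 Å). Cβ, a united side-chain centre, and the
  peptide-bond centre are rebuilt deterministically from three consecutive
  Cα positions and the residue identity.
* **Energy.** Statistical-potential–style terms in kT units: backbone
  rotational preferences over Cα 4-mers, main-chain hydrogen bonds located
  through peptide-bond centres, and a 20×20 hydrophobicity-based
  side-chain contact matrix, plus two tiers of flat-bottom distance
  restraints. Restraints are auto-generated from the input coordinates:
  every residue pair at sequence separation ≥ 5 with Cα–Cα distance in
  5–15 Å is restrained to its input distance with a 1 Å tolerance. The
  receptor gets full weight; the ligand gets tenfold weaker weights, which
  is what lets it tumble and refold.
* **Sampling.** Replica-exchange Monte Carlo (20 replicas by default) over
  a temperature ladder whose increments grow geometrically with rung
  index, combined with simulated annealing of the whole ladder (20 stages).
  Each replica starts from a different random ligand placement ~20 Å from
  the receptor surface. 2% of generated models are saved: 500 snapshots
  per replica, 10,000 pooled models per run.
* **Model selection.** For every pooled model the receptor–ligand contact
  map is computed (side-chain centres ≤ 6 Å; Ala→Cβ, Gly→Cα). The 1000
  models with the most contacts are kept, clustered by complete-link
  hierarchical clustering under the Jaccard distance between contact maps,
  and clusters are ranked by density = size / mean intra-cluster distance.
  Representatives of the ten densest clusters are the predictions.
* **Scoring.** CAPRI-style metrics against a reference complex: iRMSD
  (interface Cα RMSD; < 4 Å is "acceptable"), LRMSD (ligand RMSD after
  receptor superposition), LoRMSD (ligand-internal RMSD), fNAT (fraction
  of native contacts), and per-residue RMSF for ensembles.

## Worked example

Everything runs on synthetic toy complexes (ideal helices, hairpins and
helix bundles with known native poses), so no downloads are needed:

```bash
cgdock fixtures --seed 1 --out toy/
# toy complex written to toy (9 native contacts)

cgdock dock --receptor toy/receptor_input.pdb --ligand toy/ligand_input.pdb \
    --replicas 4 --annealing-steps 4 --snapshots 50 --offset 15 \
    --seed 29 --out run/
# pooled 200 models
# wrote 10 representative models to run

cgdock score --model toy/reference.pdb --reference toy/reference.pdb
# iRMSD   LRMSD   LoRMSD  fNAT
# 0.0     0.0     0.0     1.0
```

The score of the reference against itself is the identity check: all RMSD
metrics are 0 Å and all native contacts are recovered (fNAT 1.0). Scoring
a docked representative instead reports how far its interface (iRMSD), its
pose (LRMSD) and its internal ligand conformation (LoRMSD) sit from the
reference.

`run/` contains `top_models.pdb` (multi-MODEL PDB of cluster
representatives, with pseudo-atoms), `trajectory.tsv` (per-snapshot
replica, rung, temperature and energy breakdown), `clusters.tsv` (size,
density and representative per cluster) and `manifest.json` (the exact
configuration and seed needed to reproduce the run bit-identically).

The library mirrors the CLI: `make_toy_complex`, `run_docking`,
`compute_contact_map` / `select_models`, and `score_model` are the main
entry points; see the docstrings and `docs/methods.md`.

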