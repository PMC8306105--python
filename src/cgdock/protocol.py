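"""End-to-end docking orchestration.

The docking run follows the staged protocol: read and lattice-project the
two input structures, auto-generate flat-bottom restraints from the input
Ca coordinates (full-strength on the receptor, tenfold weaker on the
ligand), scatter the ligand at ``n_replicas`` random positions roughly
``start_offset`` Angstrom from the receptor surface, run replica-exchange
Monte Carlo with simulated annealing, and pool the saved snapshots from all
replicas into one model set tagged with replica, step, temperature and
energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import CGChain, chain_from_pdb, pseudo_atoms_from_xyz, project_to_lattice
from .energy import ForceField, RestraintSet, System, default_forcefield, generate_restraints
from .sampler import AnnealingSchedule, MoveSet, RemcConfig, Trajectory, run_remc

__all__ = [
    "DockingConfig",
    "PooledModel",
    "DockingResult",
    "generate_starting_structures",
    "run_docking",
]

MAX_LIGAND_COMFORTABLE = 150  # residues; larger flexible ligands get slow


@dataclass
class DockingConfig:
    receptor_path: str | Path | None = None
    ligand_path: str | Path | None = None
    receptor_chain_id: str | None = None
    ligand_chain_id: str | None = None
    # pre-built inputs (bypass PDB reading; used by fixtures and tests)
    receptor_xyz: np.ndarray | None = None
    receptor_seq: str | None = None
    ligand_xyz: np.ndarray | None = None
    ligand_seq: str | None = None

    n_replicas: int = 20
    annealing_steps: int = 20
    start_offset: float = 20.0        # A from the receptor surface
    snapshot_per_replica: int = 500
    save_fraction: float = 0.02
    t_min: float = 1.0
    t_max: float = 2.5
    ladder_ratio: float = 1.15
    cooling_factor: float = 0.96
    exchange_every: int = 250
    # restraint generation (flat-bottom, two-tier)
    min_seq_sep: int = 5
    restraint_dmin: float = 5.0
    restraint_dmax: float = 15.0
    restraint_tol: float = 1.0
    restraint_weight: float = 1.0     # kT per A of violation, receptor tier
    ligand_weight_scale: float = 0.1  # tenfold weaker ligand tier
    master_seed: int = 0
    moveset: MoveSet = field(default_factory=MoveSet)


@dataclass
class PooledModel:
    model_id: int
    replica: int
    attempt: int
    stage: int
    temperature: float
    energy: dict
    rec_ca: np.ndarray  # (n_rec, 3) A
    lig_ca: np.ndarray  # (n_lig, 3) A

    @property
    def total_energy(self) -> float:
        return self.energy["total"]


@dataclass
class DockingResult:
    models: list
    trajectory: Trajectory
    rec_seq: str
    lig_seq: str
    restraints: list
    config: DockingConfig


# ---------------------------------------------------------------------------
# starting structures
# ---------------------------------------------------------------------------

def _surface_distance(point: np.ndarray, receptor_atoms: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(receptor_atoms - point, axis=1)))


def generate_starting_structures(
    receptor: CGChain,
    ligand: CGChain,
    n: int,
    offset: float = 20.0,
    rng: np.random.Generator | None = None,
    tol: float = 2.0,
    max_tries: int = 200,
) -> list[System]:
    """Scatter the ligand at ``n`` random poses around the receptor.

    Each pose places the ligand centre at ``offset`` (within ``tol``)
    Angstrom from the receptor surface -- the minimum distance to any
    receptor Ca or side-chain pseudo-atom -- along a uniformly random
    direction, with a uniformly random ligand orientation.  Poses clashing
    with the receptor at the lattice-node level are re-drawn.
    """
    if n < 1:
        raise ValueError("need at least one starting pose")
    rng = rng or np.random.default_rng()
    rec_xyz = receptor.ca_xyz()
    rec_sc = pseudo_atoms_from_xyz(rec_xyz, receptor.sequence).sc
    rec_atoms = np.vstack([rec_xyz, rec_sc])
    rec_centre = rec_xyz.mean(axis=0)
    rec_radius = float(np.max(np.linalg.norm(rec_xyz - rec_centre, axis=1)))
    lig_xyz0 = ligand.ca_xyz()
    lig_centre0 = lig_xyz0.mean(axis=0)
    rec_nodes = {tuple(int(x) for x in p) for p in receptor.ca}

    systems = []
    for k in range(n):
        placed = None
        for _ in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # bisection for centre-to-surface distance == offset along u
            lo, hi = 0.0, rec_radius + offset + 10.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if _surface_distance(rec_centre + mid * u, rec_atoms) < offset:
                    lo = mid
                else:
                    hi = mid
            centre = rec_centre + hi * u
            rot = Rotation.random(random_state=rng).as_matrix()
            lig_xyz = (lig_xyz0 - lig_centre0) @ rot.T + centre
            lig_chain = project_to_lattice(
                lig_xyz, ligand.sequence, receptor.lattice, role="ligand"
            )
            if rec_nodes & {tuple(int(x) for x in p) for p in lig_chain.ca}:
                continue
            d = _surface_distance(lig_chain.ca_xyz().mean(axis=0), rec_atoms)
            if abs(d - offset) > tol:
                continue
            placed = lig_chain
            break
        if placed is None:
            raise RuntimeError(
                f"failed to place ligand for starting pose {k}: persistent "
                f"clash with the receptor after {max_tries} tries"
            )
        systems.append(System(receptor.copy(), placed))
    return systems


# ---------------------------------------------------------------------------
# full docking run
# ---------------------------------------------------------------------------

def _load_inputs(config: DockingConfig):
    if config.receptor_xyz is not None:
        rec_xyz, rec_seq = np.asarray(config.receptor_xyz, float), config.receptor_seq
    else:
        rec_xyz, rec_seq = chain_from_pdb(config.receptor_path, config.receptor_chain_id)
    if config.ligand_xyz is not None:
        lig_xyz, lig_seq = np.asarray(config.ligand_xyz, float), config.ligand_seq
    else:
        lig_xyz, lig_seq = chain_from_pdb(config.ligand_path, config.ligand_chain_id)
    return rec_xyz, rec_seq, lig_xyz, lig_seq


def run_docking(config: DockingConfig, ff: ForceField | None = None) -> DockingResult:
    """Run the whole docking protocol and pool the snapshots of all replicas."""
    ff = ff or default_forcefield()
    rec_xyz, rec_seq, lig_xyz, lig_seq = _load_inputs(config)
    if len(lig_xyz) > len(rec_xyz):
        warnings.warn(
            "ligand is larger than receptor; the flexible molecule should "
            "normally be the smaller one", stacklevel=2
        )
    if len(lig_xyz) > MAX_LIGAND_COMFORTABLE:
        warnings.warn(
            f"ligand has {len(lig_xyz)} residues; fully flexible ligands above "
            f"{MAX_LIGAND_COMFORTABLE} residues may be impractical", stacklevel=2
        )

    receptor = project_to_lattice(rec_xyz, rec_seq, role="receptor")
    ligand_input = project_to_lattice(lig_xyz, lig_seq, role="ligand")

    # restraints come from the *input* coordinates, before any docking motion
    rsets = [
        generate_restraints(
            rec_xyz, config.min_seq_sep, config.restraint_dmin, config.restraint_dmax,
            weight=config.restraint_weight, tol=config.restraint_tol,
            molecule="receptor", weight_scale=1.0,
        ),
        generate_restraints(
            lig_xyz, config.min_seq_sep, config.restraint_dmin, config.restraint_dmax,
            weight=config.restraint_weight, tol=config.restraint_tol,
            molecule="ligand", weight_scale=config.ligand_weight_scale,
        ),
    ]

    rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([config.master_seed, 0x5747])
    ))
    systems = generate_starting_structures(
        receptor, ligand_input, config.n_replicas, config.start_offset, rng
    )

    remc = RemcConfig(
        n_replicas=config.n_replicas,
        t_min=config.t_min,
        t_max=config.t_max,
        ladder_ratio=config.ladder_ratio,
        annealing=AnnealingSchedule(config.annealing_steps, config.cooling_factor),
        snapshots_per_replica=config.snapshot_per_replica,
        save_fraction=config.save_fraction,
        exchange_every=config.exchange_every,
        moveset=config.moveset,
        seed=config.master_seed,
    )
    traj = run_remc(systems, remc, ff, rsets)

    models = []
    for mid, frame in enumerate(traj.frames):
        models.append(PooledModel(
            model_id=mid,
            replica=frame.replica,
            attempt=frame.attempt,
            stage=frame.stage,
            temperature=frame.temperature,
            energy=frame.energy,
            rec_ca=frame.ca_lat[0].astype(float) * traj.spacing,
            lig_ca=frame.ca_lat[1].astype(float) * traj.spacing,
        ))
    return DockingResult(
        models=models,
        trajectory=traj,
        rec_seq=rec_seq,
        lig_seq=lig_seq,
        restraints=rsets,
        config=config,
    )
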