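"""Knowledge-based-style energy terms and flat-bottom distance restraints.

The energy of a receptor/ligand system is a sum of four additive classes,
all in kT units:

* ``local``    -- short-range backbone bias rewarding 4-mer pseudo-dihedrals
  in helix-like or extended windows (main-chain rotational preferences),
* ``hbond``    -- main-chain hydrogen bonds located through the peptide-bond
  centres: a pair of well-aligned bond centres at helix/sheet-like spacing
  contributes a fixed well depth,
* ``contact``  -- pairwise side-chain contact energies from a 20x20 matrix,
  evaluated between united side-chain centres within a cutoff, with a hard
  soft-core penalty below the repulsion radius,
* ``restraint``-- two-tier flat-bottom Ca-Ca distance restraints that keep
  the receptor near-rigid (weight scale 1.0) while letting the ligand refold
  almost freely (weight scale 0.1, i.e. tenfold weaker).

The contact matrix shipped here is a documented hydrophobicity-based
simplification of database-derived side-chain contact statistics: the well
depth of a pair is proportional to the product of the two residues'
normalised Kyte-Doolittle hydrophobicities.  It preserves the functional
class (hydrophobic residues drive association) while staying fully
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import AA_CODES, CGChain, pseudo_atoms_from_xyz

__all__ = [
    "ForceField",
    "Restraint",
    "RestraintSet",
    "EnergyBreakdown",
    "System",
    "default_forcefield",
    "hydrophobicity_contact_matrix",
    "generate_restraints",
    "restraint_energy",
    "contact_energy",
    "hbond_energy",
    "local_bias_energy",
    "total_energy",
]

# Kyte-Doolittle hydropathy, used to build the default contact matrix.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

AA_INDEX = {aa: i for i, aa in enumerate(AA_CODES)}


def hydrophobicity_contact_matrix(epsilon: float = 1.2) -> np.ndarray:
    """Symmetric 20x20 side-chain contact energies, kT.

    e[a, b] = -epsilon * h_a * h_b with h the Kyte-Doolittle hydropathy
    rescaled to [0, 1]; strongly hydrophobic pairs (Ile/Leu/Val/Phe) reach
    about -1 kT, polar pairs approach 0.
    """
    h = np.array([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in AA_CODES])
    return -epsilon * np.outer(h, h)


@dataclass
class ForceField:
    contact_matrix: np.ndarray = field(default_factory=hydrophobicity_contact_matrix)
    contact_cutoff: float = 6.0      # A, side-chain centre pair cutoff
    hard_core: float = 3.0           # A, soft-core radius for sc pairs
    repulsion: float = 3.0           # kT penalty per sc pair inside hard core
    hbond_dmin: float = 4.2          # A, pb-pb window
    hbond_dmax: float = 5.5
    hbond_align: float = 0.5         # minimum |cos| between the two bond vectors
    hbond_depth: float = 1.0         # kT per hydrogen bond
    local_bias: float = 0.5          # kT reward per 4-mer in a preferred window
    helix_window: tuple = (30.0, 90.0)     # degrees, pseudo-dihedral
    extended_min: float = 150.0            # degrees, |dihedral| above -> extended
    min_contact_sep: int = 3         # intra-chain sequence separation for contacts
    min_hbond_sep: int = 3           # intra-chain pb index separation for h-bonds

    def __post_init__(self):
        m = np.asarray(self.contact_matrix, dtype=float)
        if m.shape != (20, 20) or not np.allclose(m, m.T):
            raise ValueError("contact_matrix must be a symmetric 20x20 array")
        if self.contact_cutoff <= 0 or self.hard_core <= 0:
            raise ValueError("cutoffs must be positive")
        if self.hard_core >= self.contact_cutoff:
            raise ValueError("hard core must be below the contact cutoff")
        self.contact_matrix = m


_DEFAULT_FF: ForceField | None = None


def default_forcefield() -> ForceField:
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        _DEFAULT_FF = ForceField()
    return _DEFAULT_FF


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Restraint:
    i: int
    j: int
    d0: float      # reference Ca-Ca distance, A
    tol: float     # flat-bottom half-width, A
    weight: float  # kT per A of violation


@dataclass
class RestraintSet:
    restraints: list
    molecule: str = "receptor"        # "receptor" | "ligand"
    weight_scale: float = 1.0

    def __len__(self):
        return len(self.restraints)

    def arrays(self):
        """(i, j, d0, tol, w) as numpy arrays with weight_scale folded in."""
        if not self.restraints:
            z = np.empty(0)
            return z.astype(int), z.astype(int), z, z, z
        i = np.array([r.i for r in self.restraints], dtype=int)
        j = np.array([r.j for r in self.restraints], dtype=int)
        d0 = np.array([r.d0 for r in self.restraints])
        tol = np.array([r.tol for r in self.restraints])
        w = np.array([r.weight for r in self.restraints]) * self.weight_scale
        return i, j, d0, tol, w

    def to_tsv(self, path):
        import pandas as pd

        i, j, d0, tol, w = self.arrays()
        pd.DataFrame(
            {"i": i, "j": j, "d0": d0, "tol": tol, "weight": w}
        ).to_csv(path, sep="\t", index=False)


def generate_restraints(
    ca_xyz: np.ndarray,
    min_seq_sep: int = 5,
    dmin: float = 5.0,
    dmax: float = 15.0,
    weight: float = 1.0,
    tol: float = 1.0,
    molecule: str = "receptor",
    weight_scale: float = 1.0,
) -> RestraintSet:
    """Auto-generate flat-bottom restraints from input Ca coordinates.

    A pair (i, j), i < j, is restrained iff its sequence separation is at
    least ``min_seq_sep`` residues and the observed Ca-Ca distance falls in
    [dmin, dmax]; the observed distance becomes the flat-bottom centre d0.
    """
    xyz = np.asarray(ca_xyz, dtype=float)
    n = len(xyz)
    if n < min_seq_sep + 1:
        raise ValueError("chain shorter than min_seq_sep + 1")
    if not dmin < dmax:
        raise ValueError("dmin must be below dmax")
    ii, jj = np.triu_indices(n, k=min_seq_sep)
    d = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
    keep = (d >= dmin) & (d <= dmax)
    restraints = [
        Restraint(int(a), int(b), float(dd), tol, weight)
        for a, b, dd in zip(ii[keep], jj[keep], d[keep])
    ]
    if not restraints:
        import warnings

        warnings.warn("restraint generation produced an empty set", stacklevel=2)
    return RestraintSet(restraints, molecule=molecule, weight_scale=weight_scale)


def restraint_energy(ca_xyz: np.ndarray, rset: RestraintSet) -> float:
    """Flat-bottom penalty: zero within d0 +/- tol, linear outside."""
    i, j, d0, tol, w = rset.arrays()
    if len(i) == 0:
        return 0.0
    xyz = np.asarray(ca_xyz, dtype=float)
    d = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    viol = np.maximum(np.abs(d - d0) - tol, 0.0)
    return float(np.sum(w * viol))


# ---------------------------------------------------------------------------
# contact energy
# ---------------------------------------------------------------------------

def _as_chain_lists(positions, sequences):
    if isinstance(sequences, str):
        return [np.asarray(positions, dtype=float)], [sequences]
    return [np.asarray(p, dtype=float) for p in positions], list(sequences)


def _pair_energy_matrix(sc, codes, chain_ids, resi, ff: ForceField) -> np.ndarray:
    """Dense pairwise contact-energy matrix (zero diagonal, symmetric)."""
    d = np.linalg.norm(sc[:, None, :] - sc[None, :, :], axis=-1)
    same = chain_ids[:, None] == chain_ids[None, :]
    sep = np.abs(resi[:, None] - resi[None, :])
    eligible = (~same) | (sep >= ff.min_contact_sep)
    np.fill_diagonal(eligible, False)
    e = np.zeros_like(d)
    well = eligible & (d > ff.hard_core) & (d <= ff.contact_cutoff)
    core = eligible & (d <= ff.hard_core)
    e[well] = ff.contact_matrix[codes[:, None], codes[None, :]][well]
    e[core] = ff.repulsion
    return e


def contact_energy(sc_positions, sequence, ff: ForceField | None = None) -> float:
    """Sum of side-chain contact energies over all eligible pairs.

    Accepts a single chain (array + string) or lists of both for a
    multi-chain system.  Intra-chain pairs require sequence separation of at
    least ``ff.min_contact_sep``; all inter-chain pairs are eligible.
    """
    ff = ff or default_forcefield()
    chains, seqs = _as_chain_lists(sc_positions, sequence)
    sc = np.concatenate(chains, axis=0)
    codes = np.array([AA_INDEX[a] for s in seqs for a in s])
    chain_ids = np.concatenate([np.full(len(s), k) for k, s in enumerate(seqs)])
    resi = np.concatenate([np.arange(len(s)) for s in seqs])
    e = _pair_energy_matrix(sc, codes, chain_ids, resi, ff)
    return float(e.sum() / 2.0)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_pair_matrix(pb, u, bond_chain, bond_idx, ff: ForceField) -> np.ndarray:
    d = np.linalg.norm(pb[:, None, :] - pb[None, :, :], axis=-1)
    align = np.abs(u @ u.T)
    same = bond_chain[:, None] == bond_chain[None, :]
    sep = np.abs(bond_idx[:, None] - bond_idx[None, :])
    eligible = (~same) | (sep >= ff.min_hbond_sep)
    np.fill_diagonal(eligible, False)
    hb = eligible & (d >= ff.hbond_dmin) & (d <= ff.hbond_dmax) & (align >= ff.hbond_align)
    return np.where(hb, -ff.hbond_depth, 0.0)


def hbond_energy(ca_positions, ff: ForceField | None = None) -> float:
    """Main-chain hydrogen-bond energy from peptide-bond centres.

    A bond pair forms a hydrogen bond when the two Ca-Ca midpoints lie
    within [hbond_dmin, hbond_dmax] and the bond vectors are aligned
    (|cos| >= hbond_align); each such pair contributes -hbond_depth.
    In an ideal alpha-helix this fires for (i, i+3) midpoint pairs, so a
    helix scores strictly below the same sequence fully extended.
    """
    ff = ff or default_forcefield()
    chains = [np.asarray(c, dtype=float) for c in (
        ca_positions if isinstance(ca_positions, (list, tuple)) else [ca_positions]
    )]
    pbs, us, bc, bi = [], [], [], []
    for k, ca in enumerate(chains):
        if len(ca) < 2:
            continue
        b = np.diff(ca, axis=0)
        u = b / np.linalg.norm(b, axis=1, keepdims=True)
        pbs.append(0.5 * (ca[:-1] + ca[1:]))
        us.append(u)
        bc.append(np.full(len(b), k))
        bi.append(np.arange(len(b)))
    if not pbs:
        return 0.0
    m = _hbond_pair_matrix(
        np.concatenate(pbs), np.concatenate(us), np.concatenate(bc), np.concatenate(bi), ff
    )
    return float(m.sum() / 2.0)


# ---------------------------------------------------------------------------
# local backbone bias
# ---------------------------------------------------------------------------

def _pseudo_dihedrals(ca: np.ndarray) -> np.ndarray:
    """Ca pseudo-dihedral (degrees) for every 4-mer; empty for n < 4."""
    if len(ca) < 4:
        return np.empty(0)
    b0 = ca[1:-2] - ca[:-3]
    b1 = ca[2:-1] - ca[1:-2]
    b2 = ca[3:] - ca[2:-1]
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    m = np.cross(n0, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n0, n1)
    y = np.einsum("ij,ij->i", m, n1)
    return np.degrees(np.arctan2(y, x))


def _local_bias_terms(ca: np.ndarray, ff: ForceField) -> np.ndarray:
    # helix window applies to |phi|: both chiralities are rewarded, a common
    # coarse-potential simplification
    phi = np.abs(_pseudo_dihedrals(np.asarray(ca, dtype=float)))
    lo, hi = ff.helix_window
    helixlike = (phi >= lo) & (phi <= hi)
    extended = phi >= ff.extended_min
    return np.where(helixlike | extended, -ff.local_bias, 0.0)


def local_bias_energy(ca_positions, sequence=None, ff: ForceField | None = None) -> float:
    """Backbone rotational-preference bias, additive per Ca 4-mer.

    Each 4-mer whose pseudo-dihedral falls in the helix-like window or the
    extended window is rewarded by -local_bias kT.  Chains shorter than 4
    residues contribute nothing.
    """
    ff = ff or default_forcefield()
    chains = (
        ca_positions if isinstance(ca_positions, (list, tuple)) else [ca_positions]
    )
    return float(sum(_local_bias_terms(np.asarray(c, dtype=float), ff).sum() for c in chains))


# ---------------------------------------------------------------------------
# system and total energy
# ---------------------------------------------------------------------------

@dataclass
class System:
    """A receptor plus (optionally) a ligand sharing one lattice frame."""

    receptor: CGChain
    ligand: CGChain | None = None

    @property
    def chains(self) -> list:
        return [self.receptor] if self.ligand is None else [self.receptor, self.ligand]

    def ca_xyz_list(self) -> list:
        return [c.ca_xyz() for c in self.chains]

    def sequences(self) -> list:
        return [c.sequence for c in self.chains]

    def copy(self) -> "System":
        return System(self.receptor.copy(), self.ligand.copy() if self.ligand else None)


@dataclass
class EnergyBreakdown:
    local: float
    hbond: float
    contact: float
    restraint: float

    @property
    def total(self) -> float:
        return self.local + self.hbond + self.contact + self.restraint

    def as_dict(self) -> dict:
        return {
            "local": self.local,
            "hbond": self.hbond,
            "contact": self.contact,
            "restraint": self.restraint,
            "total": self.total,
        }


def total_energy(system: System, ff: ForceField | None = None, rsets=()) -> EnergyBreakdown:
    """Full (non-incremental) energy evaluation of a system.

    ``rsets`` maps each restraint set to the chain named by its ``molecule``
    field.  This direct evaluation is the correctness reference for the
    sampler's incremental bookkeeping.
    """
    ff = ff or default_forcefield()
    ca_list = system.ca_xyz_list()
    seqs = system.sequences()
    sc_list = [pseudo_atoms_from_xyz(ca, s).sc for ca, s in zip(ca_list, seqs)]
    by_role = {c.role: ca for c, ca in zip(system.chains, ca_list)}
    restraint = 0.0
    for rset in rsets:
        if rset.molecule not in by_role:
            raise ValueError(f"restraint set targets absent molecule {rset.molecule!r}")
        restraint += restraint_energy(by_role[rset.molecule], rset)
    return EnergyBreakdown(
        local=local_bias_energy(ca_list, ff=ff),
        hbond=hbond_energy(ca_list, ff=ff),
        contact=contact_energy(sc_list, seqs, ff=ff),
        restraint=restraint,
    )
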