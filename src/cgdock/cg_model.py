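"""Reduced protein representation on a fine cubic lattice.

A protein chain is reduced to its C-alpha trace, with consecutive beads
restricted to an underlying high-resolution cubic lattice.  The lattice is
fine enough (default spacing 0.61 Angstrom) that the virtual Ca-Ca bond may
fluctuate slightly around its physical value of ~3.8 A while the set of
allowed bond orientations stays large.  From the Ca trace three classes of
pseudo-atoms are rebuilt deterministically:

* ``cb``  -- the C-beta position, from the local backbone frame,
* ``sc``  -- a united side-chain centre, along the C-beta direction at a
  residue-type-specific distance (Gly collapses onto Ca, Ala onto Cb),
* ``pb``  -- the peptide-bond centre, the midpoint of each Ca-Ca bond,
  used to locate main-chain hydrogen bonds.

All quantities are in Angstrom unless stated otherwise; lattice coordinates
are integer triples in units of the lattice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AA_CODES",
    "LatticeSpec",
    "Residue",
    "CGChain",
    "PseudoAtoms",
    "ChainError",
    "default_lattice",
    "project_to_lattice",
    "rebuild_pseudo_atoms",
    "chain_from_pdb",
]

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

# Distance (A) from Ca to the united side-chain centre along the Cb
# direction, one entry per residue type.  Idealised-geometry simplification
# of database-derived side-chain centroids: 0 for Gly (sc == Ca), the Cb
# distance for Ala (sc == Cb), and increasing with side-chain size.
CB_DISTANCE = 1.53
SC_DISTANCE = {
    "G": 0.0, "A": 1.53, "S": 1.9, "C": 2.1, "T": 1.9, "V": 2.0,
    "P": 1.9, "D": 2.5, "N": 2.5, "I": 2.3, "L": 2.6, "E": 3.1,
    "Q": 3.1, "M": 2.9, "H": 3.1, "K": 3.5, "F": 3.4, "R": 4.1,
    "Y": 3.8, "W": 3.9,
}


class ChainError(ValueError):
    """Raised for chains violating geometric or sequence preconditions."""


@dataclass(frozen=True)
class LatticeSpec:
    """Cubic lattice with a finite set of allowed Ca-Ca bond vectors.

    ``allowed_vectors`` contains every integer displacement whose length,
    scaled by ``spacing``, lies in ``[min_bond, max_bond]``; the set is
    closed under sign flips and axis permutations by construction.
    """

    spacing: float = 0.61
    min_bond: float = 3.5
    max_bond: float = 4.1
    allowed_vectors: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.allowed_vectors is None:
            object.__setattr__(self, "allowed_vectors", self._enumerate_vectors())
        vecs = np.asarray(self.allowed_vectors, dtype=np.int64)
        object.__setattr__(self, "allowed_vectors", vecs)
        lengths = np.linalg.norm(vecs, axis=1) * self.spacing
        if not ((lengths >= self.min_bond - 1e-9) & (lengths <= self.max_bond + 1e-9)).all():
            raise ValueError("allowed vector outside the bond-length band")

    def _enumerate_vectors(self) -> np.ndarray:
        lo = self.min_bond / self.spacing
        hi = self.max_bond / self.spacing
        r = int(np.ceil(hi))
        grid = np.arange(-r, r + 1)
        vx, vy, vz = np.meshgrid(grid, grid, grid, indexing="ij")
        vecs = np.stack([vx.ravel(), vy.ravel(), vz.ravel()], axis=1)
        norms = np.linalg.norm(vecs, axis=1)
        keep = (norms >= lo) & (norms <= hi)
        vecs = vecs[keep]
        # canonical deterministic order
        order = np.lexsort((vecs[:, 2], vecs[:, 1], vecs[:, 0]))
        return vecs[order].astype(np.int64)

    @property
    def vector_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(c) for c in v) for v in self.allowed_vectors}


_DEFAULT_LATTICE: LatticeSpec | None = None


def default_lattice() -> LatticeSpec:
    """The shared default lattice (0.61 A spacing, 3.5-4.1 A bonds)."""
    global _DEFAULT_LATTICE
    if _DEFAULT_LATTICE is None:
        _DEFAULT_LATTICE = LatticeSpec()
    return _DEFAULT_LATTICE


@dataclass(frozen=True)
class Residue:
    index: int
    aa: str

    def __post_init__(self):
        if self.aa not in AA_CODES:
            raise ChainError(f"unknown amino-acid code {self.aa!r} at residue {self.index}")


@dataclass
class CGChain:
    """One protein chain as a lattice Ca trace plus sequence and role."""

    residues: list[Residue]
    ca: np.ndarray          # (n, 3) integer lattice coordinates
    role: str = "receptor"  # "receptor" | "ligand"
    lattice: LatticeSpec = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.lattice is None:
            self.lattice = default_lattice()
        self.ca = np.asarray(self.ca, dtype=np.int64)
        if self.role not in ("receptor", "ligand"):
            raise ChainError(f"role must be receptor or ligand, got {self.role!r}")
        if len(self.residues) != len(self.ca):
            raise ChainError("residue list and coordinate array length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_xyz(self) -> np.ndarray:
        """Ca coordinates in Angstrom (float)."""
        return self.ca.astype(float) * self.lattice.spacing

    def validate(self) -> None:
        """Raise ChainError on any violated chain invariant."""
        if len(self) < 2:
            raise ChainError("chain too short")
        allowed = self.lattice.vector_set
        diffs = np.diff(self.ca, axis=0)
        for k, d in enumerate(diffs):
            if tuple(int(c) for c in d) not in allowed:
                raise ChainError(
                    f"bond between residues {k} and {k + 1} is not an allowed lattice vector"
                )
        seen = {tuple(int(c) for c in p) for p in self.ca}
        if len(seen) != len(self.ca):
            raise ChainError("excluded volume violated: coincident Ca beads")

    def copy(self) -> "CGChain":
        return CGChain(list(self.residues), self.ca.copy(), self.role, self.lattice)


@dataclass
class PseudoAtoms:
    """Derived pseudo-atom coordinates (Angstrom)."""

    cb: np.ndarray  # (n, 3)
    sc: np.ndarray  # (n, 3)
    pb: np.ndarray  # (n-1, 3) bond midpoints


# ---------------------------------------------------------------------------
# lattice projection
# ---------------------------------------------------------------------------

def project_to_lattice(
    ca_xyz: np.ndarray,
    sequence: str,
    lattice: LatticeSpec | None = None,
    role: str = "receptor",
) -> CGChain:
    """Project continuous Ca coordinates onto the lattice.

    Greedy per-bead fit: the first bead is rounded to the nearest lattice
    node; each subsequent bead picks the allowed bond vector bringing it
    closest to its target position (ties broken lexicographically; nodes
    already occupied are skipped).  Because each bead aims at its own
    absolute target, projection error does not accumulate along the chain.
    """
    lattice = lattice or default_lattice()
    xyz = np.asarray(ca_xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ChainError("coordinates must be an (n, 3) array")
    n = len(xyz)
    if n < 4:
        raise ChainError(f"chain too short: {n} residues (need at least 4)")
    if len(sequence) != n:
        raise ChainError("sequence length does not match coordinates")
    dists = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    bad = np.where((dists < 2.8) | (dists > 4.6))[0]
    if bad.size:
        k = int(bad[0])
        raise ChainError(
            f"broken chain: Ca-Ca distance {dists[k]:.2f} A between residues {k} and {k + 1}"
        )

    targets = xyz / lattice.spacing
    vecs = lattice.allowed_vectors
    coords = np.empty((n, 3), dtype=np.int64)
    coords[0] = np.round(targets[0]).astype(np.int64)
    occupied = {tuple(coords[0])}
    for i in range(1, n):
        cand = coords[i - 1] + vecs
        err = np.sum((cand - targets[i]) ** 2, axis=1)
        for j in np.argsort(err, kind="stable"):
            key = (int(cand[j, 0]), int(cand[j, 1]), int(cand[j, 2]))
            if key not in occupied:
                coords[i] = cand[j]
                occupied.add(key)
                break
        else:  # pragma: no cover - would need a pathological dense fold
            raise ChainError(f"projection failed: no free lattice node for residue {i}")

    residues = [Residue(i, aa) for i, aa in enumerate(sequence)]
    chain = CGChain(residues, coords, role, lattice)
    chain.validate()
    return chain


# ---------------------------------------------------------------------------
# pseudo-atom reconstruction
# ---------------------------------------------------------------------------

def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def _local_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (bisector, normal) unit vectors from consecutive Ca triples.

    Residue i uses bonds (i-1, i) and (i, i+1); terminal residues borrow the
    frame of their nearest interior neighbour's bond pair so that every sc/cb
    is still a deterministic, rigid-motion-equivariant function of three
    consecutive Ca positions.  Collinear bond pairs have no defined frame and
    yield a zero bisector (sc and cb then collapse onto Ca).
    """
    n = len(ca)
    b = np.diff(ca, axis=0)
    bn = b / _row_norms(b)[:, None]
    # bond-pair index per residue, clamped at the termini
    idx = np.clip(np.arange(n) - 1, 0, n - 3)
    a1 = bn[idx]
    a2 = bn[idx + 1]
    bis = a1 - a2
    nrm = _cross_rows(a1, a2)
    bis_len = _row_norms(bis)[:, None]
    nrm_len = _row_norms(nrm)[:, None]
    ok = (bis_len[:, 0] > 1e-8) & (nrm_len[:, 0] > 1e-8)
    bis = np.where(ok[:, None], bis / np.where(bis_len > 0, bis_len, 1.0), 0.0)
    nrm = np.where(ok[:, None], nrm / np.where(nrm_len > 0, nrm_len, 1.0), 0.0)
    return bis, nrm


def pseudo_atoms_from_xyz(ca_xyz: np.ndarray, sequence: str) -> PseudoAtoms:
    """Rebuild cb/sc/pb pseudo-atoms from Ca coordinates in Angstrom."""
    ca = np.asarray(ca_xyz, dtype=float)
    bis, nrm = _local_frames(ca)
    # out-of-plane tilt approximating tetrahedral Cb geometry
    direction = bis + 0.57 * nrm
    dl = _row_norms(direction)[:, None]
    direction = np.where(dl > 1e-8, direction / np.where(dl > 0, dl, 1.0), 0.0)
    cb = ca + CB_DISTANCE * direction
    sc_dist = np.array([SC_DISTANCE[aa] for aa in sequence])
    sc = ca + sc_dist[:, None] * direction
    pb = 0.5 * (ca[:-1] + ca[1:])
    return PseudoAtoms(cb=cb, sc=sc, pb=pb)


def rebuild_pseudo_atoms(chain: CGChain) -> PseudoAtoms:
    """Rebuild pseudo-atoms for a lattice chain (returned in Angstrom)."""
    return pseudo_atoms_from_xyz(chain.ca_xyz(), chain.sequence)


# ---------------------------------------------------------------------------
# PDB intake
# ---------------------------------------------------------------------------

def chain_from_pdb(path: str | Path, chain_id: str | None = None):
    """Read one chain's Ca trace and sequence from a PDB file.

    Returns ``(ca_xyz, sequence)`` with residues ordered by (resSeq, iCode).
    HETATM records, waters and alternate locations other than '' / 'A' are
    ignored.  A standard residue without a Ca atom is a chain gap and is
    rejected.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain_id is None:
        if len(chains) != 1:
            raise ChainError(
                f"file has chains {sorted(chains)}; specify chain_id"
            )
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise ChainError(f"unknown chain id {chain_id!r}; file has {sorted(chains)}")

    entries = []
    for res in chains[chain_id]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        name = res.get_resname().strip()
        if name not in THREE_TO_ONE:
            continue
        if "CA" not in res:
            raise ChainError(
                f"chain gap: residue {name} {resseq}{icode.strip()} has no Ca atom"
            )
        atom = res["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get("A") if atom.disordered_has_id("A") else atom.selected_child
        entries.append(((resseq, icode), THREE_TO_ONE[name], atom.get_coord().astype(float)))

    if not entries:
        raise ChainError(f"chain {chain_id!r} contains no standard residues")
    entries.sort(key=lambda e: e[0])
    seq = "".join(e[1] for e in entries)
    xyz = np.array([e[2] for e in entries])
    return xyz, seq
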