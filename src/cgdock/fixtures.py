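"""Synthetic toy complexes and decoy ensembles for tests and desk-scale runs.

Toy proteins are built from ideal Ca geometry: alpha-helices with a rise of
1.5 A and 100 degrees of turn per residue (radius chosen so the virtual
Ca-Ca bond is 3.8 A), beta-hairpins from two antiparallel 3.8 A-spaced
strands joined by a two-bond turn, and straight extended chains.  A toy
complex packs a ligand helix/hairpin against a receptor so that the two
molecules share a nonempty side-chain contact interface; "unbound-like"
inputs are produced by adding a smooth random backbone deformation scaled
to a requested superposed RMSD.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import AA_CODES, pseudo_atoms_from_xyz
from .metrics import irmsd, lormsd, fnat, score_model
from .postprocess import compute_contact_map

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "ideal_helix",
    "ideal_hairpin",
    "extended_chain",
    "random_sequence",
    "make_toy_complex",
    "make_decoy_ensemble",
]

HELIX_RISE = 1.5          # A per residue
HELIX_TURN = 100.0        # degrees per residue
HELIX_RADIUS = 2.28       # A; gives a 3.8 A virtual bond
STRAND_SPACING = 3.8      # A between consecutive strand residues


def ideal_helix(n: int) -> np.ndarray:
    """Ideal alpha-helical Ca trace along +z, n residues."""
    k = np.arange(n)
    theta = np.radians(HELIX_TURN) * k
    return np.stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * k,
    ], axis=1)


def ideal_hairpin(n: int) -> np.ndarray:
    """Two antiparallel strands joined by a single-residue turn, along +x."""
    if n < 8:
        raise ValueError("hairpin needs at least 8 residues")
    n1 = (n - 1) // 2
    n2 = n - 1 - n1
    # 0.5 A zigzag in z breaks collinearity so side-chain frames are defined
    z1 = 0.5 * (-1.0) ** np.arange(n1)
    z2 = 0.5 * (-1.0) ** np.arange(n2)
    s1 = np.stack([STRAND_SPACING * np.arange(n1), np.zeros(n1), z1], axis=1)
    tip_x = STRAND_SPACING * (n1 - 1) + 2.93
    turn = np.array([[tip_x, 2.4, 0.0]])
    s2 = np.stack([STRAND_SPACING * (n1 - 1 - np.arange(n2)),
                   np.full(n2, 4.8), z2], axis=1)
    return np.concatenate([s1, turn, s2], axis=0)


def extended_chain(n: int) -> np.ndarray:
    """Fully extended (straight) Ca trace, 3.8 A spacing."""
    return np.stack([STRAND_SPACING * np.arange(n),
                     np.zeros(n), np.zeros(n)], axis=1)


def helix_bundle(n: int, axis_sep: float = 9.5) -> np.ndarray:
    """Compact three-helix bundle: a globular toy receptor.

    Three antiparallel helices with axes ``axis_sep`` apart on a triangle,
    joined by straight linkers; the inter-helix Ca distances populate the
    5-15 A restraint window, so the auto-generated restraint net locks the
    fold the way it does for a real globular domain.
    """
    if n < 20:
        raise ValueError("bundle needs at least 20 residues")
    offsets = [
        np.array([0.0, 0.0, 0.0]),
        np.array([axis_sep, 0.0, 0.0]),
        np.array([0.5 * axis_sep, 0.866 * axis_sep, 0.0]),
    ]
    seg = (n - 4) // 3
    sizes = [seg, seg, n - 4 - 2 * seg]
    pieces = []
    prev_end = None
    for k, (size, off) in enumerate(zip(sizes, offsets)):
        h = ideal_helix(size)
        if k % 2 == 1:
            h = h[::-1].copy()          # antiparallel packing
            h[:, 2] -= h[0, 2] - (prev_end[2] if prev_end is not None else 0.0)
        h = h + off
        if prev_end is not None:
            # straight 2-residue linker from the previous helix end
            gap = h[0] - prev_end
            for f in (1.0 / 3.0, 2.0 / 3.0):
                pieces.append((prev_end + f * gap)[None, :])
        pieces.append(h)
        prev_end = h[-1]
    xyz = np.concatenate(pieces, axis=0)
    return xyz[:n]


_TEMPLATES = {
    "helix": ideal_helix,
    "hairpin": ideal_hairpin,
    "extended": extended_chain,
    "bundle": helix_bundle,
}


def random_sequence(n: int, rng: np.random.Generator, avoid: str = "") -> str:
    pool = [a for a in AA_CODES if a not in avoid]
    return "".join(rng.choice(pool) for _ in range(n))


@dataclass
class ToyComplexSpec:
    receptor_size: int = 30
    ligand_size: int = 12
    receptor_template: str = "helix"
    ligand_template: str = "helix"
    perturbation: float = 1.0      # requested unbound-input RMSD, A
    min_contacts: int = 4          # native interface size floor
    seed: int = 0

    def __post_init__(self):
        if self.receptor_size < 8 or self.ligand_size < 8:
            raise ValueError("toy molecules need at least 8 residues")
        for t in (self.receptor_template, self.ligand_template):
            if t not in _TEMPLATES:
                raise ValueError(f"unknown template {t!r}")


@dataclass
class ToyComplex:
    rec_ref: np.ndarray
    lig_ref: np.ndarray
    rec_seq: str
    lig_seq: str
    rec_input: np.ndarray
    lig_input: np.ndarray
    native_contacts: frozenset = field(default_factory=frozenset)
    spec: ToyComplexSpec | None = None


def _hinge_deform(xyz: np.ndarray, hinges, scale: float) -> np.ndarray:
    """Rotate each chain tail about an interior pivot; bond lengths are exact."""
    from scipy.spatial.transform import Rotation

    out = xyz.copy()
    for k, axis, angle in hinges:
        rot = Rotation.from_rotvec(axis * angle * scale).as_matrix()
        out[k:] = (out[k:] - out[k]) @ rot.T + out[k]
    return out


def _perturb_to_rmsd(xyz: np.ndarray, target: float, rng: np.random.Generator,
                     n_hinges: int = 4) -> np.ndarray:
    """Hinge-bending deformation scaled so the superposed RMSD hits ``target``.

    Hinge rotations preserve every virtual bond exactly, emulating the
    backbone flexibility of an unbound structure without breaking the chain.
    """
    if target <= 0:
        return xyz.copy()
    n = len(xyz)
    for _ in range(20):
        hinges = []
        for k in sorted(rng.choice(np.arange(2, n - 2), size=min(n_hinges, n - 4),
                                   replace=False)):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            hinges.append((int(k), axis, float(rng.normal())))
        lo, hi = 0.0, 4.0
        for _ in range(60):
            s = 0.5 * (lo + hi)
            if lormsd(_hinge_deform(xyz, hinges, s), xyz) < target:
                lo = s
            else:
                hi = s
        cand = _hinge_deform(xyz, hinges, 0.5 * (lo + hi))
        if abs(lormsd(cand, xyz) - target) < 0.05 * max(target, 1.0):
            return cand
    raise RuntimeError("could not reach the requested perturbation amplitude")


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build a reference toy complex plus perturbed unbound-like inputs.

    The ligand approaches the receptor along +x; the approach distance is
    the smallest one with no side-chain clash (min sc-sc distance >= 3.2 A)
    and at least ``min_contacts`` native contacts.
    """
    rng = np.random.default_rng(spec.seed)
    rec = _TEMPLATES[spec.receptor_template](spec.receptor_size)
    lig0 = _TEMPLATES[spec.ligand_template](spec.ligand_size)
    rec_seq = random_sequence(spec.receptor_size, rng)
    lig_seq = random_sequence(spec.ligand_size, rng)

    # centre the ligand next to the receptor's mid-height, approach along +x;
    # scan separation and ligand azimuth for the clash-free pose (min sc-sc
    # distance >= 3.0 A) with the largest native interface
    lig0 = lig0 - lig0.mean(axis=0)
    rec_mid = rec.mean(axis=0)
    rec_sc = pseudo_atoms_from_xyz(rec, rec_seq).sc
    best = None
    for sep in np.arange(6.0, 16.01, 0.5):
        for az in np.arange(0.0, 360.0, 45.0):
            t = np.radians(az)
            rot = np.array([
                [np.cos(t), -np.sin(t), 0.0],
                [np.sin(t), np.cos(t), 0.0],
                [0.0, 0.0, 1.0],
            ])
            cand = lig0 @ rot.T + rec_mid + np.array([sep + HELIX_RADIUS, 0.0, 0.0])
            lig_sc = pseudo_atoms_from_xyz(cand, lig_seq).sc
            dmin = np.min(np.linalg.norm(rec_sc[:, None] - lig_sc[None, :], axis=-1))
            if dmin < 3.0:
                continue
            cm = compute_contact_map(rec, rec_seq, cand, lig_seq)
            if best is None or len(cm.contacts) > len(best[1]):
                best = (cand, cm.contacts)
    if best is None or len(best[1]) < spec.min_contacts:
        raise RuntimeError(
            "no clash-free pose with the requested number of native contacts; "
            "use larger molecules or a smaller min_contacts"
        )
    lig, native = best

    rec_input = _perturb_to_rmsd(rec, spec.perturbation, rng)
    lig_input = _perturb_to_rmsd(lig, spec.perturbation, rng)
    return ToyComplex(
        rec_ref=rec, lig_ref=lig, rec_seq=rec_seq, lig_seq=lig_seq,
        rec_input=rec_input, lig_input=lig_input,
        native_contacts=frozenset(native), spec=spec,
    )


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def _rotate_about(xyz: np.ndarray, centre: np.ndarray, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(axis / np.linalg.norm(axis) * angle).as_matrix()
    return (xyz - centre) @ rot.T + centre


def make_decoy_ensemble(complex_: ToyComplex, n: int,
                        noise_levels=(0.5, 2.0, 8.0),
                        seed: int = 0):
    """Decoy models with a known fNAT/iRMSD spread.

    Decoy 0 is the reference itself (fNAT 1); decoy 1 swings the ligand to
    the opposite receptor face (fNAT 0); the rest perturb the ligand pose
    rigidly with rotation/translation amplitudes cycled through
    ``noise_levels``.  Returns ``(models, labels)`` where models are
    (rec_xyz, lig_xyz) pairs and labels is one metrics dict per decoy.
    """
    if n < 2:
        raise ValueError("need at least two decoys (near-native and far)")
    rng = np.random.default_rng(seed)
    rec, lig = complex_.rec_ref, complex_.lig_ref
    rec_centre = rec.mean(axis=0)
    models = [(rec.copy(), lig.copy())]
    far = _rotate_about(lig, rec_centre, np.array([0.0, 0.0, 1.0]), np.pi)
    models.append((rec.copy(), far))
    k = 0
    while len(models) < n:
        level = noise_levels[k % len(noise_levels)]
        k += 1
        axis = rng.normal(size=3)
        angle = level * 0.08 * rng.normal()
        shift = level * 0.4 * rng.normal(size=3)
        cand = _rotate_about(lig, lig.mean(axis=0), axis, angle) + shift
        models.append((rec.copy(), cand))
    labels = []
    for rec_m, lig_m in models:
        rep = score_model(rec_m, lig_m, rec, lig, complex_.rec_seq, complex_.lig_seq)
        labels.append(rep.as_dict())
    return models, labels
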