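"""CAPRI-style quality metrics for docking models against a reference complex.

All RMSD-type metrics use least-squares (Kabsch) superposition restricted to
proper rotations:

* iRMSD  -- RMSD over interface Ca atoms (residues of either molecule whose
  side-chain centres come within 6 A across the interface in the reference),
  after jointly superposing the model interface onto the reference interface,
* LRMSD  -- ligand Ca RMSD after superposing the receptors only,
* LoRMSD -- ligand-internal Ca RMSD after superposing the ligand onto the
  reference ligand (conformational change, pose-independent),
* fNAT   -- fraction of the reference's side-chain-centre contacts (6 A)
  reproduced by the model,
* RMSF   -- per-residue root variance of an ensemble around the mean
  structure after per-frame superposition.

A model with iRMSD below 4 A counts as acceptable quality under the CAPRI
convention; `MetricsReport.acceptable` exposes that flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .postprocess import compute_contact_map

__all__ = [
    "SuperpositionResult",
    "MetricsReport",
    "superpose",
    "interface_residues",
    "irmsd",
    "lrmsd",
    "lormsd",
    "rmsf",
    "fnat",
    "score_model",
]

ACCEPTABLE_IRMSD = 4.0  # A, CAPRI "acceptable quality" threshold
CONTACT_CUTOFF = 6.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # (3, 3), proper (det = +1)
    translation: np.ndarray
    rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


@dataclass
class MetricsReport:
    irmsd: float
    lrmsd: float
    lormsd: float
    fnat: float
    rmsf: np.ndarray | None = None

    @property
    def acceptable(self) -> bool:
        return self.irmsd < ACCEPTABLE_IRMSD

    def as_dict(self) -> dict:
        return {
            "iRMSD": self.irmsd, "LRMSD": self.lrmsd,
            "LoRMSD": self.lormsd, "fNAT": self.fnat,
        }


def superpose(x: np.ndarray, y: np.ndarray) -> SuperpositionResult:
    """Least-squares fit of ``x`` onto ``y`` over proper rotations.

    Returns the transform minimising RMSD(R x + t, y); reflections are never
    used, so a mirrored structure keeps a nonzero residual.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(x) < 3:
        raise ValueError("need at least three points for a superposition")
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(y - cy, x - cx)
    rmat = rot.as_matrix()
    t = cy - cx @ rmat.T
    rmsd = float(rssd / np.sqrt(len(x)))
    return SuperpositionResult(rotation=rmat, translation=t, rmsd=rmsd)


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def interface_residues(
    rec_ca: np.ndarray, rec_seq: str, lig_ca: np.ndarray, lig_seq: str,
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Interface residue indices (receptor, ligand) of a reference complex.

    A residue is part of the interface when any of its side-chain-centre
    distances across the interface is at most ``cutoff``.
    """
    cm = compute_contact_map(rec_ca, rec_seq, lig_ca, lig_seq, cutoff=cutoff)
    rec = sorted({i for i, _ in cm.contacts})
    lig = sorted({j for _, j in cm.contacts})
    return np.array(rec, dtype=int), np.array(lig, dtype=int)


def irmsd(model_rec: np.ndarray, model_lig: np.ndarray,
          ref_rec: np.ndarray, ref_lig: np.ndarray,
          rec_seq: str, lig_seq: str, cutoff: float = CONTACT_CUTOFF) -> float:
    """Interface RMSD: joint superposition of model interface Ca onto the
    reference interface Ca (receptor and ligand interface residues together)."""
    ri, li = interface_residues(ref_rec, rec_seq, ref_lig, lig_seq, cutoff)
    if ri.size + li.size < 3:
        raise ValueError("reference complex has no interface at this cutoff")
    ref = np.vstack([np.asarray(ref_rec, float)[ri], np.asarray(ref_lig, float)[li]])
    mod = np.vstack([np.asarray(model_rec, float)[ri], np.asarray(model_lig, float)[li]])
    return superpose(mod, ref).rmsd


def lrmsd(model_rec: np.ndarray, model_lig: np.ndarray,
          ref_rec: np.ndarray, ref_lig: np.ndarray) -> float:
    """Ligand RMSD after superposing the receptors (no further fitting)."""
    fit = superpose(np.asarray(model_rec, float), np.asarray(ref_rec, float))
    return _plain_rmsd(fit.apply(np.asarray(model_lig, float)), np.asarray(ref_lig, float))


def lormsd(model_lig: np.ndarray, ref_lig: np.ndarray) -> float:
    """Ligand-only RMSD: internal conformation change, pose removed."""
    return superpose(np.asarray(model_lig, float), np.asarray(ref_lig, float)).rmsd


def rmsf(frames, reference: np.ndarray | None = None, n_iter: int = 2) -> np.ndarray:
    """Per-residue root variance of an ensemble around its mean structure.

    Each frame is superposed onto the reference; the reference defaults to
    the ensemble mean, refined by ``n_iter`` rounds of fit-then-average.
    """
    frames = [np.asarray(f, float) for f in frames]
    if not frames:
        raise ValueError("empty trajectory")
    if reference is None:
        reference = frames[0]
        for _ in range(n_iter):
            fitted = [superpose(f, reference).apply(f) for f in frames]
            reference = np.mean(fitted, axis=0)
    fitted = np.stack([superpose(f, reference).apply(f) for f in frames])
    mean = fitted.mean(axis=0)
    var = np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)
    return np.sqrt(var)


def fnat(model_rec: np.ndarray, model_lig: np.ndarray,
         ref_rec: np.ndarray, ref_lig: np.ndarray,
         rec_seq: str, lig_seq: str, cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of reference contacts reproduced by the model."""
    ref_cm = compute_contact_map(ref_rec, rec_seq, ref_lig, lig_seq, cutoff=cutoff)
    if not ref_cm.contacts:
        raise ValueError("reference complex has no contacts at this cutoff")
    mod_cm = compute_contact_map(model_rec, rec_seq, model_lig, lig_seq, cutoff=cutoff)
    return len(ref_cm.contacts & mod_cm.contacts) / len(ref_cm.contacts)


def score_model(model_rec, model_lig, ref_rec, ref_lig, rec_seq, lig_seq,
                cutoff: float = CONTACT_CUTOFF) -> MetricsReport:
    """All single-model metrics against a reference complex."""
    return MetricsReport(
        irmsd=irmsd(model_rec, model_lig, ref_rec, ref_lig, rec_seq, lig_seq, cutoff),
        lrmsd=lrmsd(model_rec, model_lig, ref_rec, ref_lig),
        lormsd=lormsd(model_lig, ref_lig),
        fnat=fnat(model_rec, model_lig, ref_rec, ref_lig, rec_seq, lig_seq, cutoff),
    )
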