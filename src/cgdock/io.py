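"""Shared I/O plumbing: PDB writing, run reports, run manifests.

Reading standard PDB files is delegated to Biopython (see
:func:`cgdock.cg_model.chain_from_pdb`).  Writing uses a minimal
fixed-width ATOM-record writer because the coarse-grained models (Ca trace
plus CB/SC/PB pseudo-atoms) are not a standard entity; coordinates are
written at the PDB's native 0.001 A precision and round-trip exactly at
that precision through the reader.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cg_model import pseudo_atoms_from_xyz

__all__ = [
    "write_ca_pdb",
    "write_models_pdb",
    "write_trajectory_log",
    "build_report",
    "write_report",
    "read_report",
    "RunManifest",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def _atom_line(serial, name, resname, chain_id, resseq, xyz, element):
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain_id}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def _chain_records(lines, serial, chain_id, seq, ca_xyz, pseudo: bool):
    pa = pseudo_atoms_from_xyz(ca_xyz, seq) if pseudo else None
    for i, aa in enumerate(seq):
        res = _ONE_TO_THREE[aa]
        lines.append(_atom_line(serial, "CA", res, chain_id, i + 1, ca_xyz[i], "C"))
        serial += 1
        if pseudo:
            if aa != "G":
                lines.append(_atom_line(serial, "CB", res, chain_id, i + 1, pa.cb[i], "C"))
                serial += 1
            if aa not in "GA":
                lines.append(_atom_line(serial, "SC", res, chain_id, i + 1, pa.sc[i], "C"))
                serial += 1
            if i < len(seq) - 1:
                lines.append(_atom_line(serial, "PB", res, chain_id, i + 1, pa.pb[i], "C"))
                serial += 1
    lines.append("TER\n")
    return serial


def write_ca_pdb(path, chains, pseudo_atoms: bool = False) -> None:
    """Write one model: ``chains`` is a list of (chain_id, sequence, ca_xyz)."""
    lines: list[str] = []
    serial = 1
    for chain_id, seq, xyz in chains:
        serial = _chain_records(lines, serial, chain_id, seq, np.asarray(xyz, float),
                                pseudo_atoms)
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def write_models_pdb(path, models, pseudo_atoms: bool = False) -> None:
    """Write a multi-MODEL ensemble; each model is a list of chain tuples."""
    lines: list[str] = []
    for k, chains in enumerate(models, start=1):
        lines.append(f"MODEL     {k:4d}\n")
        serial = 1
        for chain_id, seq, xyz in chains:
            serial = _chain_records(lines, serial, chain_id, seq,
                                    np.asarray(xyz, float), pseudo_atoms)
        lines.append("ENDMDL\n")
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def read_models_pdb(path):
    """Read every MODEL of a (multi-model) PDB.

    Returns a list of models, each an ordered dict chain_id -> (ca_xyz, seq);
    only Ca atoms of standard residues are taken.
    """
    from Bio.PDB import PDBParser

    from .cg_model import THREE_TO_ONE

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    out = []
    for model in structure:
        chains = {}
        for chain in model:
            coords, seq = [], []
            for res in chain:
                het, resseq, icode = res.id
                if het.strip() or res.get_resname().strip() not in THREE_TO_ONE:
                    continue
                if "CA" not in res:
                    continue
                coords.append(res["CA"].get_coord().astype(float))
                seq.append(THREE_TO_ONE[res.get_resname().strip()])
            if coords:
                chains[chain.id] = (np.array(coords), "".join(seq))
        if chains:
            out.append(chains)
    return out


def write_trajectory_log(path, trajectory) -> None:
    """TSV log: one row per snapshot with rung, temperature and energies."""
    rows = [
        {
            "replica": f.replica, "stage": f.stage, "attempt": f.attempt,
            "rung": f.rung, "temperature": f.temperature, **f.energy,
        }
        for f in trajectory.frames
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


REPORT_COLUMNS = [
    "case", "n_models", "average_LoRMSD",
    "best_iRMSD_all", "best_LRMSD_all", "best_fNAT_all",
    "best_iRMSD_top10", "best_LRMSD_top10", "best_fNAT_top10",
]


def build_report(case: str, all_metrics: list, top_metrics: list) -> pd.DataFrame:
    """One summary row: average ligand flexibility plus the best-of columns.

    ``all_metrics`` / ``top_metrics`` are lists of metric dicts (keys iRMSD,
    LRMSD, LoRMSD, fNAT) for the full pool and the 10 top-scored models.
    """
    if not all_metrics:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    row = {
        "case": case,
        "n_models": len(all_metrics),
        "average_LoRMSD": float(np.mean([m["LoRMSD"] for m in all_metrics])),
        "best_iRMSD_all": float(min(m["iRMSD"] for m in all_metrics)),
        "best_LRMSD_all": float(min(m["LRMSD"] for m in all_metrics)),
        "best_fNAT_all": float(max(m["fNAT"] for m in all_metrics)),
        "best_iRMSD_top10": float(min(m["iRMSD"] for m in top_metrics)) if top_metrics else np.nan,
        "best_LRMSD_top10": float(min(m["LRMSD"] for m in top_metrics)) if top_metrics else np.nan,
        "best_fNAT_top10": float(max(m["fNAT"] for m in top_metrics)) if top_metrics else np.nan,
    }
    return pd.DataFrame([row], columns=REPORT_COLUMNS)


def write_report(path, report: pd.DataFrame) -> None:
    report.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    config: dict
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    versions: dict = field(default_factory=lambda: {
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
    })

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))
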