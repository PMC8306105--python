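"""Contact-map analysis of pooled docking models.

The pooled snapshot set is reduced to binding modes in four steps: compute
the receptor-ligand side-chain contact map of every model (6 A cutoff;
Ala's side chain is its C-beta, Gly's its C-alpha), keep the 1000 models
with the most inter-molecular contacts (dropping transient, weakly bound
poses), cluster the surviving maps by complete-link hierarchical clustering
under the Jaccard distance, and rank clusters by density -- member count
divided by the mean pairwise distance between members.  The representative
of each cluster is the member closest (in summed Jaccard distance) to its
co-members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cg_model import pseudo_atoms_from_xyz

__all__ = [
    "ContactMap",
    "Cluster",
    "compute_contact_map",
    "contact_count_filter",
    "jaccard_distance",
    "complete_link_cluster",
    "rank_and_select",
    "select_models",
]

CONTACT_CUTOFF = 6.0  # A between side-chain centres
TOP_MODELS_KEPT = 1000
DEFAULT_N_CLUSTERS = 30
TOP_CLUSTERS = 10


@dataclass
class ContactMap:
    """Inter-molecular residue-residue contacts of one model."""

    contacts: frozenset          # {(receptor residue, ligand residue), ...}
    model_id: int
    energy: float = 0.0

    def __len__(self):
        return len(self.contacts)


@dataclass
class Cluster:
    members: list                # model ids
    density: float
    representative: int          # model id
    mean_distance: float


def compute_contact_map(
    rec_ca: np.ndarray,
    rec_seq: str,
    lig_ca: np.ndarray,
    lig_seq: str,
    cutoff: float = CONTACT_CUTOFF,
    model_id: int = 0,
    energy: float = 0.0,
) -> ContactMap:
    """Residue pairs whose side-chain centres are at most ``cutoff`` apart.

    Side-chain centres follow the reduced representation: the united
    side-chain pseudo-atom, which coincides with C-beta for Ala and with
    C-alpha for Gly.
    """
    rsc = pseudo_atoms_from_xyz(np.asarray(rec_ca, float), rec_seq).sc
    lsc = pseudo_atoms_from_xyz(np.asarray(lig_ca, float), lig_seq).sc
    d = np.linalg.norm(rsc[:, None, :] - lsc[None, :, :], axis=-1)
    pairs = np.argwhere(d <= cutoff)
    contacts = frozenset((int(i), int(j)) for i, j in pairs)
    return ContactMap(contacts=contacts, model_id=model_id, energy=energy)


def contact_count_filter(maps: list, keep: int = TOP_MODELS_KEPT) -> list:
    """Keep the ``keep`` maps with the largest contact counts.

    Ties are broken deterministically by (lower energy, then model id).  If
    fewer than ``keep`` maps are supplied, all are kept with a warning.
    """
    if len(maps) < keep:
        warnings.warn(
            f"only {len(maps)} maps supplied, fewer than keep={keep}; keeping all",
            stacklevel=2,
        )
        keep = len(maps)
    ranked = sorted(maps, key=lambda m: (-len(m.contacts), m.energy, m.model_id))
    return ranked[:keep]


def jaccard_distance(a: ContactMap | frozenset, b: ContactMap | frozenset) -> float:
    """1 - |A n B| / |A u B|; two empty maps are at distance 0 by convention."""
    sa = a.contacts if isinstance(a, ContactMap) else frozenset(a)
    sb = b.contacts if isinstance(b, ContactMap) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return 1.0 - len(sa & sb) / union


def _distance_matrix(maps: list) -> np.ndarray:
    """All-pairs Jaccard distances via a binary membership matrix."""
    n = len(maps)
    universe = sorted(set().union(*(m.contacts for m in maps)))
    if not universe:
        return np.zeros((n, n))
    index = {c: k for k, c in enumerate(universe)}
    m = np.zeros((n, len(universe)), dtype=np.float32)
    for i, cm in enumerate(maps):
        for c in cm.contacts:
            m[i, index[c]] = 1.0
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(d, 0.0)
    return d.astype(float)


def complete_link_cluster(maps: list, n_clusters: int = DEFAULT_N_CLUSTERS,
                          distance_threshold: float | None = None) -> list:
    """Complete-link hierarchical clustering of contact maps.

    Maps are canonically ordered by model id before clustering, so the
    result does not depend on input order.  Returns a list of lists of
    model ids; cut either at ``n_clusters`` or at ``distance_threshold``.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    maps = sorted(maps, key=lambda m: m.model_id)
    if len(maps) == 1:
        return [[maps[0].model_id]]
    d = _distance_matrix(maps)
    z = linkage(squareform(d, checks=False), method="complete")
    if distance_threshold is not None:
        labels = fcluster(z, t=distance_threshold, criterion="distance")
    else:
        labels = fcluster(z, t=min(n_clusters, len(maps)), criterion="maxclust")
    out: dict[int, list] = {}
    for m, lab in zip(maps, labels):
        out.setdefault(int(lab), []).append(m.model_id)
    return [sorted(v) for _, v in sorted(out.items())]


def rank_and_select(clusters: list, maps: list, k: int = TOP_CLUSTERS) -> list:
    """Rank clusters by density and pick one representative model per cluster.

    Density is the member count divided by the mean pairwise Jaccard
    distance between members; singletons get density 0 by convention and
    rank last.  The representative minimises the summed Jaccard distance to
    its co-members (ties: lower energy, then model id).  Returns the top
    ``k`` Cluster records, density-descending.
    """
    by_id = {m.model_id: m for m in maps}
    records = []
    for members in clusters:
        ms = [by_id[i] for i in members]
        n = len(ms)
        if n == 1:
            records.append(Cluster(members, 0.0, ms[0].model_id, 0.0))
            continue
        d = _distance_matrix(ms)
        mean_d = float(d[np.triu_indices(n, 1)].mean())
        density = n / mean_d if mean_d > 0 else float(n) / 1e-9
        sums = d.sum(axis=1)
        order = sorted(
            range(n), key=lambda t: (sums[t], ms[t].energy, ms[t].model_id)
        )
        records.append(Cluster(members, density, ms[order[0]].model_id, mean_d))
    records.sort(key=lambda c: (-c.density, c.representative))
    if len(records) < k:
        warnings.warn(
            f"only {len(records)} clusters available, fewer than {k}", stacklevel=2
        )
    return records[:k]


def select_models(maps: list, keep: int = TOP_MODELS_KEPT,
                  n_clusters: int = DEFAULT_N_CLUSTERS, k: int = TOP_CLUSTERS) -> list:
    """Full filter -> cluster -> rank pipeline; top-k cluster records."""
    kept = contact_count_filter(maps, keep=keep)
    clusters = complete_link_cluster(kept, n_clusters=n_clusters)
    return rank_and_select(clusters, kept, k=k)
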