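"""Monte Carlo move set and Replica Exchange with simulated annealing.

The sampler operates on lattice Ca traces.  All movers are local and stay
on-lattice by construction:

* ``single``    -- re-draw one interior bead among all lattice nodes
  compatible with both flanking bonds,
* ``two``       -- re-draw two consecutive interior beads,
* ``end``       -- re-draw a terminal bead around its single neighbour,
* ``fragment``  -- translate a contiguous fragment by one lattice unit
  (whole-chain translation when the fragment spans the chain),
* ``rigid_translate`` / ``rigid_rotate`` -- rigid-body translation, or 90/180/270
  degree lattice rotation about a randomly chosen bead, of the whole ligand.

Every mover draws uniformly from a state-independent candidate set that
contains the reverse move, so proposals are symmetric and plain Metropolis
acceptance samples the Boltzmann distribution at each rung's temperature.

Replica exchange swaps temperature assignments between adjacent rungs of a
ladder whose increments grow geometrically with rung index; simulated
annealing multiplies the whole ladder by a cooling factor after each stage.
Each replica owns an independent counter-based (Philox) random stream, so a
run is bit-reproducible from its master seed.

Energies are tracked incrementally: each move recomputes only the terms
touching the moved beads.  The cached totals are checked against a full
recomputation at every annealing stage and any divergence is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_model import (
    CGChain,
    LatticeSpec,
    _cross_rows,
    _row_norms,
    default_lattice,
    pseudo_atoms_from_xyz,
)
from .energy import (
    AA_INDEX,
    EnergyBreakdown,
    ForceField,
    System,
    default_forcefield,
    total_energy,
)

__all__ = [
    "TemperatureLadder",
    "AnnealingSchedule",
    "MoveSet",
    "RemcConfig",
    "Replica",
    "Snapshot",
    "Trajectory",
    "SimState",
    "Proposal",
    "build_temperature_ladder",
    "metropolis_accept",
    "propose_move",
    "replica_exchange_sweep",
    "run_remc",
]


# ---------------------------------------------------------------------------
# temperature ladder and annealing
# ---------------------------------------------------------------------------

@dataclass
class TemperatureLadder:
    temps: np.ndarray
    r: float
    t_min: float
    t_max: float

    def scale(self, factor: float) -> None:
        """Multiply every rung (used by simulated annealing)."""
        self.temps = self.temps * factor

    def __len__(self):
        return len(self.temps)


def build_temperature_ladder(t_min: float, t_max: float, n: int, r: float) -> TemperatureLadder:
    """Ladder with geometrically growing increments.

    The k-th increment is d0 * r**k with d0 solved from the geometric-series
    sum so that the hottest rung lands exactly on t_max.  r = 1 reduces to
    the constant-increment scheme.
    """
    if n < 2:
        raise ValueError("need at least two rungs")
    if not t_min < t_max:
        raise ValueError("degenerate ladder: t_min must be below t_max")
    if r <= 0:
        raise ValueError("ratio must be positive")
    span = t_max - t_min
    if r == 1.0:
        d0 = span / (n - 1)
    else:
        d0 = span * (1.0 - r) / (1.0 - r ** (n - 1))
    incs = d0 * r ** np.arange(n - 1)
    temps = t_min + np.concatenate([[0.0], np.cumsum(incs)])
    temps[-1] = t_max  # kill accumulated round-off
    return TemperatureLadder(temps=temps, r=r, t_min=t_min, t_max=t_max)


@dataclass
class AnnealingSchedule:
    n_steps: int = 20
    cooling_factor: float = 0.96


@dataclass
class MoveSet:
    """Weighted mover mixture; weights are normalised on construction."""

    movers: list = field(default_factory=lambda: [
        ("single", 0.50),
        ("two", 0.15),
        ("end", 0.10),
        ("fragment", 0.10),
        ("rigid_translate", 0.075),
        ("rigid_rotate", 0.075),
    ])

    def __post_init__(self):
        kinds = [k for k, w in self.movers]
        weights = np.array([w for k, w in self.movers], dtype=float)
        if (weights <= 0).any():
            raise ValueError("mover weights must be positive")
        self.kinds = kinds
        self.weights = weights / weights.sum()
        self.cum_weights = np.cumsum(self.weights)


@dataclass
class RemcConfig:
    n_replicas: int = 20
    t_min: float = 1.0
    t_max: float = 2.5
    ladder_ratio: float = 1.15
    annealing: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    snapshots_per_replica: int = 500
    save_fraction: float = 0.02
    exchange_every: int = 250
    moveset: MoveSet = field(default_factory=MoveSet)
    seed: int = 0

    @property
    def save_every(self) -> int:
        return int(round(1.0 / self.save_fraction))

    @property
    def attempts_per_replica(self) -> int:
        return self.snapshots_per_replica * self.save_every


# ---------------------------------------------------------------------------
# Metropolis
# ---------------------------------------------------------------------------

def metropolis_accept(delta_e: float, temp: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_e / temp))."""
    if temp <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / temp)


# ---------------------------------------------------------------------------
# incremental simulation state
# ---------------------------------------------------------------------------

@dataclass
class Proposal:
    kind: str
    chain: int
    moved: np.ndarray        # residue indices re-drawn by the move
    new_lat: np.ndarray      # (k, 3) candidate lattice coordinates
    delta: float | None = None


class SimState:
    """Mutable receptor(+ligand) state with incremental energy bookkeeping."""

    def __init__(self, system: System, ff: ForceField | None = None, rsets=(),):
        self.ff = ff or default_forcefield()
        self.lattice: LatticeSpec = system.receptor.lattice
        self.spacing = self.lattice.spacing
        self.chains = [c.copy() for c in system.chains]
        for c in self.chains:
            c.validate()
        self.roles = [c.role for c in self.chains]
        self.seqs = [c.sequence for c in self.chains]
        self.codes = [np.array([AA_INDEX[a] for a in s]) for s in self.seqs]
        self.ca_lat = [c.ca for c in self.chains]
        self.ca = [c.ca_xyz() for c in self.chains]
        self._rebuild_derived()
        self.occupied = {
            tuple(int(v) for v in p) for lat in self.ca_lat for p in lat
        }
        if len(self.occupied) != sum(len(l) for l in self.ca_lat):
            raise ValueError("excluded volume violated in the starting system")
        # restraints mapped to chain index by molecule role
        self._r = []
        for k, role in enumerate(self.roles):
            arrs = [rs.arrays() for rs in rsets if rs.molecule == role]
            if arrs:
                ri = np.concatenate([a[0] for a in arrs])
                rj = np.concatenate([a[1] for a in arrs])
                rd = np.concatenate([a[2] for a in arrs])
                rt = np.concatenate([a[3] for a in arrs])
                rw = np.concatenate([a[4] for a in arrs])
            else:
                ri = rj = np.empty(0, dtype=int)
                rd = rt = rw = np.empty(0)
            by_res = [[] for _ in range(len(self.seqs[k]))]
            for idx, (a, b) in enumerate(zip(ri, rj)):
                by_res[a].append(idx)
                by_res[b].append(idx)
            self._r.append((ri, rj, rd, rt, rw, [np.array(x, dtype=int) for x in by_res]))
        self._rsets = tuple(rsets)
        self._vec_arr = self.lattice.allowed_vectors
        # dense membership table: O(1) vectorised "is this an allowed bond?"
        self._vr = int(np.abs(self._vec_arr).max())
        side = 2 * self._vr + 1
        self._vlut = np.zeros((side, side, side), dtype=bool)
        shifted = self._vec_arr + self._vr
        self._vlut[shifted[:, 0], shifted[:, 1], shifted[:, 2]] = True
        # pair-count table: (ind * ind)[d] = #{v in V: d - v in V}, exact after
        # rounding since the counts are small integers
        from scipy.signal import fftconvolve

        ind = self._vlut.astype(float)
        self._plut = np.round(fftconvolve(ind, ind)).astype(np.int64)
        self._mid_cache: dict = {}
        self._pair_cache: dict = {}
        e = total_energy(self.to_system(), self.ff, self._rsets)
        self.energy = {
            "local": e.local, "hbond": e.hbond,
            "contact": e.contact, "restraint": e.restraint,
        }
        self.n_attempted = 0
        self.n_accepted = 0
        self._total_len = float(sum(len(s) for s in self.seqs))

    # -- derived coordinate caches ------------------------------------------

    def _rebuild_derived(self):
        self.sc, self.pb, self.u = [], [], []
        for ca, seq in zip(self.ca, self.seqs):
            pa = pseudo_atoms_from_xyz(ca, seq)
            b = np.diff(ca, axis=0)
            self.sc.append(pa.sc)
            self.pb.append(pa.pb)
            self.u.append(b / np.linalg.norm(b, axis=1, keepdims=True))

    def to_system(self) -> System:
        chains = [
            CGChain(list(c.residues), lat.copy(), c.role, self.lattice)
            for c, lat in zip(self.chains, self.ca_lat)
        ]
        rec = next(c for c in chains if c.role == "receptor")
        lig = next((c for c in chains if c.role == "ligand"), None)
        return System(rec, lig)

    @property
    def total_energy_cached(self) -> float:
        return sum(self.energy.values())

    def energy_breakdown(self) -> EnergyBreakdown:
        return EnergyBreakdown(
            local=self.energy["local"], hbond=self.energy["hbond"],
            contact=self.energy["contact"], restraint=self.energy["restraint"],
        )

    def check_energy(self, tol: float = 1e-6, resync: bool = False) -> None:
        ref = total_energy(self.to_system(), self.ff, self._rsets)
        cached = self.energy_breakdown()
        if abs(ref.total - cached.total) > tol * (1.0 + abs(ref.total)):
            raise RuntimeError(
                f"energy cache divergence: cached {cached.total:.9f}, "
                f"recomputed {ref.total:.9f}"
            )
        if resync:  # absorb benign float drift at stage boundaries
            self.energy = {"local": ref.local, "hbond": ref.hbond,
                           "contact": ref.contact, "restraint": ref.restraint}

    # -- affected-set partial energies --------------------------------------

    def _sc_affected(self, c: int, moved: np.ndarray) -> np.ndarray:
        n = len(self.seqs[c])
        mset = set(int(m) for m in moved)
        lo = max(0, int(moved.min()) - 3)
        hi = min(n, int(moved.max()) + 4)
        out = []
        for r in range(lo, hi):
            idx = min(max(r - 1, 0), n - 3)
            if {idx, idx + 1, idx + 2} & mset:
                out.append(r)
        return np.array(out, dtype=int)

    def _partial(self, c: int, res_a: np.ndarray, bonds: np.ndarray,
                 fourmers: np.ndarray, raff: np.ndarray) -> np.ndarray:
        """(local, hbond, contact, restraint) sums over the affected terms."""
        ff = self.ff
        out = np.zeros(4)
        ca = self.ca[c]
        # local bias over affected 4-mers
        if fourmers.size:
            k = fourmers
            b0 = ca[k + 1] - ca[k]
            b1 = ca[k + 2] - ca[k + 1]
            b2 = ca[k + 3] - ca[k + 2]
            n0 = _cross_rows(b0, b1)
            n1 = _cross_rows(b1, b2)
            m = _cross_rows(n0, b1 / _row_norms(b1)[:, None])
            phi = np.degrees(np.arctan2(
                np.einsum("ij,ij->i", m, n1), np.einsum("ij,ij->i", n0, n1)
            ))
            aphi = np.abs(phi)
            lo, hi = ff.helix_window
            pref = ((aphi >= lo) & (aphi <= hi)) | (aphi >= ff.extended_min)
            out[0] = -ff.local_bias * np.count_nonzero(pref)
        # hydrogen bonds: affected bonds vs all bonds (squared-distance window)
        if bonds.size:
            pba = self.pb[c][bonds]
            ua = self.u[c][bonds]
            dmin2, dmax2 = ff.hbond_dmin ** 2, ff.hbond_dmax ** 2
            hsum = 0.0
            for c2 in range(len(self.chains)):
                pb2, u2 = self.pb[c2], self.u[c2]
                diff = pba[:, None, :] - pb2[None, :, :]
                d2 = np.einsum("ijk,ijk->ij", diff, diff)
                hb = (d2 >= dmin2) & (d2 <= dmax2)
                if hb.any():
                    hb &= np.abs(ua @ u2.T) >= ff.hbond_align
                if c2 == c:
                    sep = np.abs(bonds[:, None] - np.arange(len(u2))[None, :])
                    hb &= sep >= ff.min_hbond_sep
                    hsum += np.count_nonzero(hb) - 0.5 * np.count_nonzero(hb[:, bonds])
                else:
                    hsum += np.count_nonzero(hb)
            out[1] = -ff.hbond_depth * hsum
        # side-chain contacts: affected residues vs all residues
        if res_a.size:
            sca = self.sc[c][res_a]
            codesa = self.codes[c][res_a]
            hc2, cut2 = ff.hard_core ** 2, ff.contact_cutoff ** 2
            csum = 0.0
            for c2 in range(len(self.chains)):
                sc2, codes2 = self.sc[c2], self.codes[c2]
                diff = sca[:, None, :] - sc2[None, :, :]
                d2 = np.einsum("ijk,ijk->ij", diff, diff)
                if c2 == c:
                    sep = np.abs(res_a[:, None] - np.arange(len(sc2))[None, :])
                    elig = sep >= ff.min_contact_sep
                    well = elig & (d2 > hc2) & (d2 <= cut2)
                    core = elig & (d2 <= hc2)
                else:
                    well = (d2 > hc2) & (d2 <= cut2)
                    core = d2 <= hc2
                e = np.zeros(d2.shape)
                if well.any():
                    e[well] = ff.contact_matrix[codesa[:, None], codes2[None, :]][well]
                e[core] = ff.repulsion
                s = e.sum()
                if c2 == c:
                    s -= 0.5 * e[:, res_a].sum()
                csum += s
            out[2] = csum
        # restraints touching the moved beads
        ri, rj, rd, rt, rw, _ = self._r[c]
        if raff.size:
            d = _row_norms(ca[ri[raff]] - ca[rj[raff]])
            out[3] = np.sum(rw[raff] * np.maximum(np.abs(d - rd[raff]) - rt[raff], 0.0))
        return out

    def _affected_sets(self, c: int, moved: np.ndarray):
        n = len(self.seqs[c])
        res_a = self._sc_affected(c, moved)
        bonds = np.unique(np.concatenate([moved - 1, moved]))
        bonds = bonds[(bonds >= 0) & (bonds <= n - 2)]
        k_lo = max(0, int(moved.min()) - 3)
        k_hi = min(n - 4, int(moved.max()))
        fourmers = np.arange(k_lo, k_hi + 1) if k_hi >= k_lo else np.empty(0, dtype=int)
        _, _, _, _, _, by_res = self._r[c]
        lists = [by_res[int(m)] for m in moved if len(by_res[int(m)])]
        raff = np.unique(np.concatenate(lists)) if lists else np.empty(0, dtype=int)
        return res_a, bonds, fourmers, raff

    # -- candidate-set caches -----------------------------------------------

    def _is_allowed(self, vecs: np.ndarray) -> np.ndarray:
        """Vectorised membership of displacement vectors in the allowed set."""
        v = np.atleast_2d(vecs) + self._vr
        inside = ((v >= 0) & (v < self._vlut.shape[0])).all(axis=1)
        out = np.zeros(len(v), dtype=bool)
        if inside.any():
            sel = v[inside]
            out[inside] = self._vlut[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def _middle_vectors(self, e: tuple) -> np.ndarray:
        """Allowed v with v in V and e - v in V (single-bead candidate set)."""
        hit = self._mid_cache.get(e)
        if hit is None:
            cand = self._vec_arr
            ok = self._is_allowed(np.asarray(e)[None, :] - cand)
            hit = cand[ok].copy()
            self._mid_cache[e] = hit
        return hit

    def _double_counts(self, e: tuple) -> np.ndarray:
        """Cumulative count of valid (v1, v2) pairs per v1 for end-to-end e.

        Lets the two-bead mover draw uniformly from the full pair set
        {(v1, v2): v1, v2, e - v1 - v2 all in V} without materialising it.
        """
        hit = self._pair_cache.get(e)
        if hit is None:
            # counts[i] = #{v2: v2 and e - v1_i - v2 both allowed}, looked up in
            # the convolution table at d = e - v1_i (offset by 2R into _plut)
            d = np.asarray(e)[None, :] - self._vec_arr + 2 * self._vr
            inside = ((d >= 0) & (d < self._plut.shape[0])).all(axis=1)
            counts = np.zeros(len(self._vec_arr), dtype=np.int64)
            sel = d[inside]
            if len(sel):
                counts[inside] = self._plut[sel[:, 0], sel[:, 1], sel[:, 2]]
            hit = np.cumsum(counts)
            self._pair_cache[e] = hit
        return hit

    def _draw_double(self, e: tuple, rng: np.random.Generator):
        """Uniform draw of (v1, v2) from the two-bead candidate set, or None."""
        cum = self._double_counts(e)
        total = int(cum[-1]) if len(cum) else 0
        if total == 0:
            return None
        u = int(rng.integers(total))
        idx = int(np.searchsorted(cum, u, side="right"))
        v1 = self._vec_arr[idx]
        offset = u - (int(cum[idx - 1]) if idx > 0 else 0)
        mids = self._middle_vectors(tuple(int(x) for x in (np.asarray(e) - v1)))
        return v1, mids[offset]

    # -- movers --------------------------------------------------------------

    def _pick_chain(self, rng: np.random.Generator) -> int:
        # probability proportional to chain length
        r = rng.random() * self._total_len
        acc = 0.0
        for k, s in enumerate(self.seqs):
            acc += len(s)
            if r < acc:
                return k
        return len(self.seqs) - 1

    def _ligand_index(self) -> int | None:
        for k, role in enumerate(self.roles):
            if role == "ligand":
                return k
        return None

    def propose(self, moveset: MoveSet, rng: np.random.Generator) -> Proposal | None:
        kind = moveset.kinds[int(np.searchsorted(moveset.cum_weights, rng.random()))]
        if kind in ("rigid_translate", "rigid_rotate"):
            c = self._ligand_index()
            if c is None:
                return None
        else:
            c = self._pick_chain(rng)
        lat = self.ca_lat[c]
        n = len(lat)
        if kind == "single":
            if n < 3:
                return None
            i = int(rng.integers(1, n - 1))
            e = tuple(int(x) for x in (lat[i + 1] - lat[i - 1]))
            cand = self._middle_vectors(e)
            if len(cand) == 0:
                return None
            v = cand[int(rng.integers(len(cand)))]
            return Proposal(kind, c, np.array([i]), (lat[i - 1] + v)[None, :])
        if kind == "two":
            if n < 4:
                return None
            i = int(rng.integers(1, n - 2))
            e = tuple(int(x) for x in (lat[i + 2] - lat[i - 1]))
            drawn = self._draw_double(e, rng)
            if drawn is None:
                return None
            v1, v2 = drawn
            p = lat[i - 1] + v1
            q = p + v2
            return Proposal(kind, c, np.array([i, i + 1]), np.stack([p, q]))
        if kind == "end":
            i = 0 if rng.random() < 0.5 else n - 1
            nb = lat[1] if i == 0 else lat[n - 2]
            v = self._vec_arr[int(rng.integers(len(self._vec_arr)))]
            return Proposal(kind, c, np.array([i]), (nb + v)[None, :])
        if kind == "fragment":
            length = int(rng.integers(2, min(n, 8) + 1))
            start = int(rng.integers(0, n - length + 1))
            moved = np.arange(start, start + length)
            axis = int(rng.integers(3))
            step = 1 if rng.random() < 0.5 else -1
            delta = np.zeros(3, dtype=np.int64)
            delta[axis] = step
            new = lat[moved] + delta
            # boundary bonds must remain allowed
            if start > 0 and not self._is_allowed(new[0] - lat[start - 1])[0]:
                return None
            if start + length < n and not self._is_allowed(lat[start + length] - new[-1])[0]:
                return None
            return Proposal(kind, c, moved, new)
        if kind == "rigid_translate":
            moved = np.arange(n)
            axis = int(rng.integers(3))
            step = int(rng.choice([-2, -1, 1, 2]))
            delta = np.zeros(3, dtype=np.int64)
            delta[axis] = step
            return Proposal(kind, c, moved, lat + delta)
        if kind == "rigid_rotate":
            moved = np.arange(n)
            k = int(rng.integers(n))         # pivot bead, fixed by the rotation
            axis = int(rng.integers(3))
            quarter = int(rng.choice([1, 2, 3]))
            rot = _lattice_rotation(axis, quarter)
            centre = lat[k]
            new = centre + (lat - centre) @ rot.T
            return Proposal(kind, c, moved, new.astype(np.int64))
        raise ValueError(f"unknown mover kind {kind!r}")  # pragma: no cover

    # -- applying moves -------------------------------------------------------

    def attempt_move(self, moveset: MoveSet, temp: float, rng: np.random.Generator) -> bool:
        """One Monte Carlo step; returns True if the move was accepted."""
        self.n_attempted += 1
        prop = self.propose(moveset, rng)
        if prop is None:
            return False
        c, moved, new = prop.chain, prop.moved, prop.new_lat
        lat = self.ca_lat[c]
        if np.array_equal(new, lat[moved]):
            self.n_accepted += 1   # null move: accepted, nothing changes
            return True
        old_keys = [tuple(int(x) for x in lat[m]) for m in moved]
        new_keys = [tuple(int(x) for x in p) for p in new]
        if len(set(new_keys)) != len(new_keys):
            return False
        blocked = self.occupied.difference(old_keys)
        if any(k in blocked for k in new_keys):
            return False

        res_a, bonds, fourmers, raff = self._affected_sets(c, moved)
        old_part = self._partial(c, res_a, bonds, fourmers, raff)

        # tentative update with slice backups
        bk_lat = lat[moved].copy()
        bk_ca = self.ca[c][moved].copy()
        bk_sc = self.sc[c][res_a].copy()
        bk_pb = self.pb[c][bonds].copy()
        bk_u = self.u[c][bonds].copy()
        lat[moved] = new
        self.ca[c][moved] = new.astype(float) * self.spacing
        self._refresh_derived(c, res_a, bonds)
        new_part = self._partial(c, res_a, bonds, fourmers, raff)
        delta = new_part - old_part
        prop.delta = float(delta.sum())

        if metropolis_accept(prop.delta, temp, rng):
            self.occupied.difference_update(old_keys)
            self.occupied.update(new_keys)
            for key, d in zip(("local", "hbond", "contact", "restraint"), delta):
                self.energy[key] += float(d)
            self.n_accepted += 1
            return True
        lat[moved] = bk_lat
        self.ca[c][moved] = bk_ca
        self.sc[c][res_a] = bk_sc
        self.pb[c][bonds] = bk_pb
        self.u[c][bonds] = bk_u
        return False

    def _refresh_derived(self, c: int, res_a: np.ndarray, bonds: np.ndarray):
        ca = self.ca[c]
        n = len(ca)
        if res_a.size:
            # rebuild frames on a minimal window; the residue->bond-pair
            # clamping matches the full chain's on this slice by construction
            lo = min(max(int(res_a.min()) - 1, 0), n - 3)
            hi = min(max(int(res_a.max()) - 1, 0), n - 3) + 2
            pa = pseudo_atoms_from_xyz(ca[lo:hi + 1], self.seqs[c][lo:hi + 1])
            self.sc[c][res_a] = pa.sc[res_a - lo]
        if bonds.size:
            b = ca[bonds + 1] - ca[bonds]
            self.pb[c][bonds] = 0.5 * (ca[bonds] + ca[bonds + 1])
            self.u[c][bonds] = b / _row_norms(b)[:, None]


def _lattice_rotation(axis: int, quarter: int) -> np.ndarray:
    c = [1, 0, -1, 0][quarter % 4]
    s = [0, 1, 0, -1][quarter % 4]
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.int64)
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=np.int64)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.int64)


def propose_move(state: SimState, moveset: MoveSet, rng: np.random.Generator) -> Proposal | None:
    """Draw one symmetric move proposal (None counts as an auto-rejection)."""
    return state.propose(moveset, rng)


# ---------------------------------------------------------------------------
# replicas and exchange
# ---------------------------------------------------------------------------

@dataclass
class Replica:
    state: SimState
    temp_index: int
    rng: np.random.Generator
    replica_id: int = 0

    @property
    def energy(self) -> float:
        return self.state.total_energy_cached


def replica_exchange_sweep(replicas: list, ladder: TemperatureLadder,
                           rng: np.random.Generator) -> int:
    """Attempt swaps between every pair of adjacent rungs; returns swap count.

    Swap of rungs (k, k+1) is accepted with min(1, exp((b_k - b_k1)(E_k - E_k1)))
    where b = 1/T.  Only temperature assignments are exchanged, so the
    multiset of conformations is preserved.
    """
    by_rung = {rep.temp_index: rep for rep in replicas}
    if sorted(by_rung) != list(range(len(replicas))):
        raise ValueError("temperature assignment is not a permutation of rungs")
    n_swapped = 0
    for k in range(len(replicas) - 1):
        a, b = by_rung[k], by_rung[k + 1]
        beta_a = 1.0 / ladder.temps[k]
        beta_b = 1.0 / ladder.temps[k + 1]
        arg = (beta_a - beta_b) * (a.energy - b.energy)
        if arg >= 0 or rng.random() < np.exp(arg):
            a.temp_index, b.temp_index = k + 1, k
            by_rung[k], by_rung[k + 1] = b, a
            n_swapped += 1
    return n_swapped


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    replica: int
    stage: int
    attempt: int
    rung: int
    temperature: float
    energy: dict
    ca_lat: list  # per-chain (n, 3) int arrays


@dataclass
class Trajectory:
    frames: list
    sequences: list
    roles: list
    spacing: float
    config: "RemcConfig"

    def __len__(self):
        return len(self.frames)

    def replica_frames(self, replica: int) -> list:
        return [f for f in self.frames if f.replica == replica]

    def ca_xyz(self, frame: Snapshot, chain: int) -> np.ndarray:
        return frame.ca_lat[chain].astype(float) * self.spacing


# ---------------------------------------------------------------------------
# the REMC driver
# ---------------------------------------------------------------------------

def run_remc(systems, config: RemcConfig, ff: ForceField | None = None,
             rsets=()) -> Trajectory:
    """Replica-exchange Monte Carlo with simulated annealing.

    ``systems`` is either one System (replicated across all rungs) or a list
    of ``n_replicas`` Systems, one starting arrangement per replica.  Saves
    exactly ``snapshots_per_replica`` snapshots per replica -- the configured
    ``save_fraction`` of all attempted moves -- evenly spaced over the run.
    """
    ff = ff or default_forcefield()
    if isinstance(systems, System):
        systems = [systems.copy() for _ in range(config.n_replicas)]
    if len(systems) != config.n_replicas:
        raise ValueError(
            f"need {config.n_replicas} starting systems, got {len(systems)}"
        )
    ladder = build_temperature_ladder(
        config.t_min, config.t_max, config.n_replicas, config.ladder_ratio
    )
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_replicas + 1)
    replicas = [
        Replica(
            state=SimState(sys_k, ff, rsets),
            temp_index=k,
            rng=np.random.Generator(np.random.Philox(children[k])),
            replica_id=k,
        )
        for k, sys_k in enumerate(systems)
    ]
    exchange_rng = np.random.Generator(np.random.Philox(children[-1]))

    n_stages = config.annealing.n_steps
    total = config.attempts_per_replica
    per_stage = total // n_stages
    remainder = total - per_stage * n_stages
    save_every = config.save_every
    frames: list[Snapshot] = []
    attempt = 0
    for stage in range(n_stages):
        stage_attempts = per_stage + (remainder if stage == n_stages - 1 else 0)
        for _ in range(stage_attempts):
            attempt += 1
            for rep in replicas:
                temp = float(ladder.temps[rep.temp_index])
                rep.state.attempt_move(config.moveset, temp, rep.rng)
            if attempt % config.exchange_every == 0:
                replica_exchange_sweep(replicas, ladder, exchange_rng)
            if attempt % save_every == 0:
                for rep in replicas:
                    frames.append(Snapshot(
                        replica=rep.replica_id,
                        stage=stage,
                        attempt=attempt,
                        rung=rep.temp_index,
                        temperature=float(ladder.temps[rep.temp_index]),
                        energy=rep.state.energy_breakdown().as_dict(),
                        ca_lat=[lat.copy() for lat in rep.state.ca_lat],
                    ))
        for rep in replicas:
            rep.state.check_energy(resync=True)
        if stage < n_stages - 1:
            ladder.scale(config.annealing.cooling_factor)

    state0 = replicas[0].state
    return Trajectory(
        frames=frames,
        sequences=list(state0.seqs),
        roles=list(state0.roles),
        spacing=state0.spacing,
        config=config,
    )
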