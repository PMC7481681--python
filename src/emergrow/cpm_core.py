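"""Cellular Potts lattice, effective energy and Monte Carlo dynamics.

The model represents each cell as the set of lattice sites carrying its
unique integer label (label 0 is the surrounding medium). Configurations
evolve by copy attempts: a random source site proposes to overwrite a random
von Neumann neighbour with its own label, and the proposal is accepted with
the Boltzmann-like probability ``exp(-max(0, dH)/H*)``, where ``dH`` is the
change in the effective energy

    H = sum_cells lambda_v (n_sites - v_target)^2
      + sum over ordered Moore site pairs with mismatched labels of J(tau, tau')

and ``H*`` is the intrinsic random motility (a temperature-like tolerance
for energy-increasing moves). One Monte Carlo step (MCS) performs as many
copy attempts as there are lattice sites and is the simulation time unit.

The lattice is a fixed (non-periodic) square domain; copy attempts whose
target falls outside the lattice are rejected, and sites outside the domain
contribute no contact energy.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional

import numpy as np

from ._kernels import mcs_sweep

MEDIUM = 0
LIVE = 1
DEAD = 2

#: von Neumann range-1 directions in the order consumed by the RNG stream.
VON_NEUMANN_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
MOORE_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


class ConsistencyError(RuntimeError):
    """Raised when the label raster and the agent registry disagree."""


class Agent(NamedTuple):
    type_code: int
    n_sites: int


@dataclass(frozen=True)
class CPMParams:
    """Lattice-model constants.

    ``site_length_um`` is the physical edge length of one lattice site, chosen
    so that a nominal 20 um diameter cell (314 um^2) occupies 36 sites when
    initialised as a 6x6 square. ``motility_hstar`` sets the tolerance of
    energy-increasing copies. Volume constraints apply to live cells only:
    medium and dead types carry zero constraint strength, which is what makes
    dead cells shrink away by adhesion-driven compaction.
    """

    site_length_um: float = 2.96
    motility_hstar: float = 10.0
    lambda_volume_live: float = 2.0
    lambda_volume_dead: float = 0.0
    target_volume_sites: int = 36
    j_cell_cell: float = 6.0
    j_cell_medium: float = 12.0
    j_dead_cell: Optional[float] = None
    j_dead_medium: Optional[float] = None
    j_dead_dead: Optional[float] = None

    def __post_init__(self) -> None:
        if self.motility_hstar <= 0:
            raise ValueError("motility_hstar must be positive")
        if self.target_volume_sites < 1:
            raise ValueError("target_volume_sites must be >= 1 for live cells")

    def contact_matrix(self) -> np.ndarray:
        """Symmetric 3x3 contact-energy matrix indexed by (type, type).

        Dead types default to the live-cell coefficients; the medium-medium
        entry is irrelevant (the medium is a single agent, so medium-medium
        pairs are never mismatched).
        """
        jdc = self.j_cell_cell if self.j_dead_cell is None else self.j_dead_cell
        jdm = self.j_cell_medium if self.j_dead_medium is None else self.j_dead_medium
        jdd = self.j_cell_cell if self.j_dead_dead is None else self.j_dead_dead
        j = np.zeros((3, 3), dtype=np.float64)
        j[LIVE, LIVE] = self.j_cell_cell
        j[LIVE, MEDIUM] = j[MEDIUM, LIVE] = self.j_cell_medium
        j[DEAD, LIVE] = j[LIVE, DEAD] = jdc
        j[DEAD, MEDIUM] = j[MEDIUM, DEAD] = jdm
        j[DEAD, DEAD] = jdd
        return j

    def lambda_by_type(self) -> np.ndarray:
        return np.array([0.0, self.lambda_volume_live, self.lambda_volume_dead])

    def vtarget_by_type(self) -> np.ndarray:
        return np.array([0.0, float(self.target_volume_sites), 0.0])


class LatticeState:
    """Integer-labelled lattice plus the agent registry.

    Agent ids are unique, start at 1, and are never reused within a run.
    Per-id type codes and site counts are kept in flat arrays so the Monte
    Carlo kernel can address them directly; ``agents`` presents the usual
    registry view and site sets are materialised on demand.
    """

    def __init__(self, shape: tuple[int, int], capacity: int = 64):
        self.labels = np.zeros(shape, dtype=np.int64)
        self.types_by_id = np.zeros(capacity, dtype=np.int8)
        self.volumes_by_id = np.zeros(capacity, dtype=np.int64)
        self.volumes_by_id[MEDIUM] = self.labels.size
        self._active: set[int] = set()
        self.next_id = 1
        self.mcs_clock = 0

    # -- registry ---------------------------------------------------------

    def _ensure_capacity(self, n: int) -> None:
        cap = self.types_by_id.shape[0]
        if n < cap:
            return
        new_cap = max(2 * cap, n + 1)
        self.types_by_id = np.concatenate(
            [self.types_by_id, np.zeros(new_cap - cap, dtype=np.int8)]
        )
        self.volumes_by_id = np.concatenate(
            [self.volumes_by_id, np.zeros(new_cap - cap, dtype=np.int64)]
        )

    def add_cell(self, sites: np.ndarray, cell_type: int = LIVE) -> int:
        """Register a new agent occupying ``sites`` (array of (row, col))."""
        sites = np.atleast_2d(np.asarray(sites, dtype=np.int64))
        rows, cols = sites[:, 0], sites[:, 1]
        if np.any(self.labels[rows, cols] != MEDIUM):
            raise ValueError("new cell sites must currently be medium")
        cid = self.next_id
        self.next_id += 1
        self._ensure_capacity(cid)
        self.labels[rows, cols] = cid
        self.types_by_id[cid] = cell_type
        self.volumes_by_id[cid] = sites.shape[0]
        self.volumes_by_id[MEDIUM] -= sites.shape[0]
        self._active.add(cid)
        return cid

    def split_cell(self, cell_id: int, sites: np.ndarray) -> int:
        """Reassign ``sites`` of ``cell_id`` to a fresh agent id (same type)."""
        sites = np.atleast_2d(np.asarray(sites, dtype=np.int64))
        rows, cols = sites[:, 0], sites[:, 1]
        if np.any(self.labels[rows, cols] != cell_id):
            raise ValueError("sites to split off must belong to the parent cell")
        if sites.shape[0] >= self.volumes_by_id[cell_id]:
            raise ValueError("cannot split off all of a cell's sites")
        new_id = self.next_id
        self.next_id += 1
        self._ensure_capacity(new_id)
        self.labels[rows, cols] = new_id
        self.types_by_id[new_id] = self.types_by_id[cell_id]
        self.volumes_by_id[new_id] = sites.shape[0]
        self.volumes_by_id[cell_id] -= sites.shape[0]
        self._active.add(new_id)
        return new_id

    def set_type(self, cell_id: int, cell_type: int) -> None:
        if cell_id not in self._active:
            raise KeyError(f"agent {cell_id} is not in the registry")
        self.types_by_id[cell_id] = cell_type

    def sites_of(self, cell_id: int) -> np.ndarray:
        return np.argwhere(self.labels == cell_id)

    def cell_ids(self, cell_type: Optional[int] = None) -> list[int]:
        ids = sorted(self._active)
        if cell_type is None:
            return ids
        return [i for i in ids if self.types_by_id[i] == cell_type]

    @property
    def agents(self) -> Dict[int, Agent]:
        return {
            cid: Agent(int(self.types_by_id[cid]), int(self.volumes_by_id[cid]))
            for cid in sorted(self._active)
        }

    def prune_empty(self) -> list[int]:
        """Drop agents whose site set has become empty; returns removed ids."""
        removed = [cid for cid in self._active if self.volumes_by_id[cid] == 0]
        for cid in removed:
            self._active.discard(cid)
        return removed

    # -- derived views ----------------------------------------------------

    def type_raster(self) -> np.ndarray:
        """Per-site type code (0 medium, 1 live, 2 dead)."""
        return self.types_by_id[self.labels]

    @property
    def n_non_medium_sites(self) -> int:
        return int(self.labels.size - self.volumes_by_id[MEDIUM])

    def validate(self) -> None:
        """Check the disjoint-cover invariant between raster and registry."""
        ids, counts = np.unique(self.labels, return_counts=True)
        raster = {int(i): int(c) for i, c in zip(ids, counts) if i != MEDIUM}
        for cid in raster:
            if cid not in self._active:
                raise ConsistencyError(f"label {cid} present in raster but not registry")
        for cid in self._active:
            n = raster.get(cid, 0)
            if n != self.volumes_by_id[cid]:
                raise ConsistencyError(
                    f"agent {cid}: registry volume {self.volumes_by_id[cid]}"
                    f" != raster count {n}"
                )
        n_medium = int(np.count_nonzero(self.labels == MEDIUM))
        if n_medium != self.volumes_by_id[MEDIUM]:
            raise ConsistencyError("medium site count out of sync")

    def copy(self) -> "LatticeState":
        new = LatticeState.__new__(LatticeState)
        new.labels = self.labels.copy()
        new.types_by_id = self.types_by_id.copy()
        new.volumes_by_id = self.volumes_by_id.copy()
        new._active = set(self._active)
        new.next_id = self.next_id
        new.mcs_clock = self.mcs_clock
        return new


def acceptance_probability(delta_h: float, hstar: float) -> float:
    """Metropolis-style acceptance probability exp(-max(0, dH)/H*)."""
    if hstar <= 0:
        raise ValueError("hstar must be positive")
    return float(np.exp(-max(0.0, delta_h) / hstar))


def total_effective_energy(state: LatticeState, params: CPMParams) -> float:
    """Global effective energy: volume constraints plus ordered contact pairs.

    The contact term sums over every ordered pair of Moore-adjacent sites with
    mismatched agent ids, i.e. each unordered interface pair counts twice,
    exactly as the double sum in the energy definition reads.
    """
    labels = state.labels
    present = set(int(i) for i in np.unique(labels)) - {MEDIUM}
    missing = present - state._active
    if missing:
        raise ConsistencyError(f"labels missing from registry: {sorted(missing)}")

    lam = params.lambda_by_type()
    vt = params.vtarget_by_type()
    e_vol = 0.0
    for cid, agent in state.agents.items():
        lam_t = lam[agent.type_code]
        if lam_t > 0:
            e_vol += lam_t * (agent.n_sites - vt[agent.type_code]) ** 2

    j = params.contact_matrix()
    tcode = state.type_raster()
    e_contact = 0.0
    h, w = labels.shape
    for dr, dc in MOORE_OFFSETS:
        r0, r1 = max(0, dr), min(h, h + dr)
        c0, c1 = max(0, dc), min(w, w + dc)
        a = (slice(r0, r1), slice(c0, c1))
        b = (slice(r0 - dr, r1 - dr), slice(c0 - dc, c1 - dc))
        mism = labels[a] != labels[b]
        e_contact += j[tcode[a][mism], tcode[b][mism]].sum()
    return float(e_vol + e_contact)


def delta_energy_for_copy(
    state: LatticeState,
    source_site: tuple[int, int],
    target_site: tuple[int, int],
    params: CPMParams,
) -> float:
    """Energy change if ``source_site``'s label were copied onto ``target_site``.

    Computed from local terms only; the state is not modified. Mirrors the
    compiled sweep kernel exactly.
    """
    h, w = state.labels.shape
    r, c = source_site
    r2, c2 = target_site
    for rr, cc in ((r, c), (r2, c2)):
        if not (0 <= rr < h and 0 <= cc < w):
            raise IndexError(f"site {(rr, cc)} outside the lattice")
    if abs(r - r2) + abs(c - c2) != 1:
        raise ValueError("target must be a von Neumann range-1 neighbour of source")

    sid = int(state.labels[r, c])
    tid = int(state.labels[r2, c2])
    if sid == tid:
        return 0.0
    lam = params.lambda_by_type()
    vt = params.vtarget_by_type()
    j = params.contact_matrix()
    ts = int(state.types_by_id[sid])
    tt = int(state.types_by_id[tid])
    dh = 0.0
    if tid != MEDIUM and lam[tt] > 0:
        n = float(state.volumes_by_id[tid])
        dh += lam[tt] * ((n - 1.0 - vt[tt]) ** 2 - (n - vt[tt]) ** 2)
    if sid != MEDIUM and lam[ts] > 0:
        n = float(state.volumes_by_id[sid])
        dh += lam[ts] * ((n + 1.0 - vt[ts]) ** 2 - (n - vt[ts]) ** 2)
    for dr, dc in MOORE_OFFSETS:
        r3, c3 = r2 + dr, c2 + dc
        if not (0 <= r3 < h and 0 <= c3 < w):
            continue
        nid = int(state.labels[r3, c3])
        tn = int(state.types_by_id[nid])
        e_new = 0.0 if nid == sid else j[ts, tn]
        e_old = 0.0 if nid == tid else j[tt, tn]
        dh += 2.0 * (e_new - e_old)
    return float(dh)


def monte_carlo_step(
    state: LatticeState, params: CPMParams, rng: np.random.Generator
) -> LatticeState:
    """Advance the lattice by one MCS (|L| copy attempts), in place.

    Per MCS the generator is consumed in a fixed order: |L| flat source
    indices, |L| direction draws, |L| acceptance uniforms. Agents whose site
    set becomes empty are removed from the registry.
    """
    n = state.labels.size
    src = rng.integers(0, n, size=n)
    nbr = rng.integers(0, 4, size=n)
    u = rng.random(n)
    mcs_sweep(
        state.labels,
        state.types_by_id,
        state.volumes_by_id,
        params.lambda_by_type(),
        params.vtarget_by_type(),
        params.contact_matrix(),
        src,
        nbr,
        u,
        params.motility_hstar,
    )
    state.prune_empty()
    state.mcs_clock += 1
    return state
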