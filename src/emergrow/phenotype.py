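"""Stochastic intracellular responses: Gaussian proliferation/death rules.

Each cell type is described by two Gaussian response curves over the cell's
mean oxygen concentration: one for proliferation and one for death. A
response is parametrised biologically by

* a target concentration (uM) at which the response peaks,
* a response width (uM): the offset from the target at which the per-MCS
  probability falls to a cutoff (default once per million MCS), and
* a population multiplier n: the factor by which a population held at the
  target concentration multiplies over 10 000 MCS under exponential growth,
  which fixes the per-MCS peak probability q = n**(1/10000) - 1.

The Gaussian width then follows as sigma = w / sqrt(ln q - ln p_cutoff), so
that the probability at |c - target| = w is exactly the cutoff.

Division is geometric: a cell splits along its minor principal axis (from
the second central moments of its site coordinates), the positive-side half
becoming a fresh agent. Death converts a cell to the dead type: zero volume
constraint, no respiration, excluded from response sampling; the lattice
dynamics then gradually remove it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Literal

import numpy as np

from . import cpm_core, oxygen_pde

MIN_DIVISION_SITES = 4


@dataclass(frozen=True)
class ResponseSpec:
    """Biological parametrisation of one Gaussian response."""

    target_uM: float
    width_uM: float
    multiplier: float
    cutoff_prob: float = 1e-6

    def __post_init__(self) -> None:
        if self.width_uM <= 0:
            raise ValueError("response width must be positive")
        if self.multiplier <= 1:
            raise ValueError("population multiplier must exceed 1")
        if not (0 < self.cutoff_prob < 1):
            raise ValueError("cutoff probability must lie in (0, 1)")


@dataclass(frozen=True)
class BuiltResponse:
    """ResponseSpec together with its derived Gaussian parameters."""

    spec: ResponseSpec
    peak_prob_q: float
    gaussian_sigma_uM: float


def build_profile(spec: ResponseSpec) -> BuiltResponse:
    """Derive (per-MCS peak probability, Gaussian sigma) from a ResponseSpec."""
    q = math.expm1(math.log(spec.multiplier) / 10_000.0)
    if q <= spec.cutoff_prob:
        raise ValueError(
            f"peak probability {q:g} does not exceed the cutoff "
            f"{spec.cutoff_prob:g}; the Gaussian width is undefined"
        )
    sigma = spec.width_uM / math.sqrt(math.log(q) - math.log(spec.cutoff_prob))
    return BuiltResponse(spec=spec, peak_prob_q=q, gaussian_sigma_uM=sigma)


def response_probability(mean_c_uM, response: BuiltResponse):
    """Per-MCS response probability at mean concentration ``mean_c_uM`` (uM)."""
    c = np.asarray(mean_c_uM, dtype=np.float64)
    z = (c - response.spec.target_uM) / response.gaussian_sigma_uM
    p = response.peak_prob_q * np.exp(-z * z)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(mean_c_uM) else p


@dataclass(frozen=True)
class PhenotypeProfile:
    """One cell type: a proliferation response and a death response."""

    name: str
    proliferation: BuiltResponse
    death: BuiltResponse

    @classmethod
    def from_specs(
        cls, name: str, proliferation: ResponseSpec, death: ResponseSpec
    ) -> "PhenotypeProfile":
        return cls(name, build_profile(proliferation), build_profile(death))


#: Named profile presets. Control proliferates near the environmental oxygen
#: level (target 200 uM) and dies near anoxia (target 0); the variations each
#: move one parameter, in an endpoint ("1") and midpoint ("2") version.
PROFILE_PRESETS = {
    "Control": ((200.0, 100.0, 6.0), (0.0, 50.0, 6.0)),
    "Decrease 1": ((200.0, 100.0, 4.0), (0.0, 50.0, 6.0)),
    "Decrease 2": ((200.0, 100.0, 2.0), (0.0, 50.0, 6.0)),
    "Shift 1": ((210.0, 100.0, 6.0), (0.0, 50.0, 6.0)),
    "Shift 2": ((205.0, 100.0, 6.0), (0.0, 50.0, 6.0)),
    "Shrink 1": ((200.0, 80.0, 6.0), (0.0, 50.0, 6.0)),
    "Shrink 2": ((200.0, 90.0, 6.0), (0.0, 50.0, 6.0)),
    "Increase 1": ((200.0, 100.0, 6.0), (0.0, 50.0, 8.0)),
    "Increase 2": ((200.0, 100.0, 6.0), (0.0, 50.0, 7.0)),
    "Expand 1": ((200.0, 100.0, 6.0), (0.0, 100.0, 6.0)),
    "Expand 2": ((200.0, 100.0, 6.0), (0.0, 75.0, 6.0)),
}


def get_preset(name: str) -> PhenotypeProfile:
    try:
        prolif, death = PROFILE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {', '.join(PROFILE_PRESETS)}"
        ) from None
    return PhenotypeProfile.from_specs(
        name, ResponseSpec(*prolif), ResponseSpec(*death)
    )


@dataclass(frozen=True)
class ResponseEvent:
    cell_id: int
    kind: Literal["proliferate", "die"]
    mcs: int


def sample_responses(
    state: cpm_core.LatticeState,
    field: oxygen_pde.OxygenField,
    profile: PhenotypeProfile,
    rng: np.random.Generator,
) -> List[ResponseEvent]:
    """Draw this MCS's death and proliferation events for all live cells.

    Death is sampled before proliferation and a cell that dies emits no
    proliferation event. The generator is consumed as two vectorised uniform
    draws (death, then proliferation) over the live cells in ascending id
    order. Dead cells are never sampled.
    """
    live_ids = np.array(state.cell_ids(cpm_core.LIVE), dtype=np.int64)
    if live_ids.size == 0:
        return []
    means_uM = oxygen_pde.mean_concentration_by_cell(field, state)[live_ids] * 1000.0
    p_die = response_probability(means_uM, profile.death)
    died = rng.random(live_ids.size) < p_die
    p_div = response_probability(means_uM, profile.proliferation)
    divides = (~died) & (rng.random(live_ids.size) < p_div)

    events: List[ResponseEvent] = []
    mcs = state.mcs_clock
    for cid in live_ids[died]:
        events.append(ResponseEvent(int(cid), "die", mcs))
    for cid in live_ids[divides]:
        events.append(ResponseEvent(int(cid), "proliferate", mcs))
    return events


def _principal_axes(sites: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and major-axis unit vector from second central moments.

    Degenerate (equal-eigenvalue) shapes take the minor axis along the
    lattice row (y) direction, i.e. the major axis along columns. The major
    axis sign is normalised for determinism.
    """
    centroid = sites.mean(axis=0)
    x = sites - centroid
    cov = x.T @ x / sites.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) < 1e-9:
        major = np.array([0.0, 1.0])
    else:
        major = evecs[:, 1]
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    return centroid, major


def divide_cell(
    state: cpm_core.LatticeState, cell_id: int, params: cpm_core.CPMParams
) -> int | None:
    """Split ``cell_id`` along its minor axis; returns the new agent id.

    Sites with positive projection on the major axis through the centroid are
    reassigned to a fresh agent; sites exactly on the cut line stay with the
    parent. Both daughters keep the live type and the full target volume.
    Cells below the minimum size guard (4 sites) are skipped (returns None)
    to avoid accidental loss of viability through tiny fragments.
    """
    sites = state.sites_of(cell_id)
    if sites.shape[0] < MIN_DIVISION_SITES:
        return None
    centroid, major = _principal_axes(sites.astype(np.float64))
    proj = (sites - centroid) @ major
    new_sites = sites[proj > 1e-9]
    if new_sites.shape[0] == 0 or new_sites.shape[0] == sites.shape[0]:
        return None  # degenerate arrangement; skip rather than create an empty daughter
    return state.split_cell(cell_id, new_sites)


def kill_cell(
    state: cpm_core.LatticeState, cell_id: int, params: cpm_core.CPMParams
) -> None:
    """Convert a live cell to its dead type (no-op with a warning if already dead)."""
    if state.types_by_id[cell_id] == cpm_core.DEAD:
        warnings.warn(f"cell {cell_id} is already dead", stacklevel=2)
        return
    state.set_type(cell_id, cpm_core.DEAD)
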