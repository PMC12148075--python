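"""The simulated well: IFN-gamma voxel field, antibody, motion and contacts.

The well is a closed rectangular box discretized into 50 um voxels.  The
IFN-gamma concentration field evolves by explicit 7-point-stencil diffusion
with zero-flux (reflecting) boundaries plus first-order decay; secretion
deposits mass into the voxel containing the secreting cell.  The soluble
anti-PD-L1 antibody is treated as a single well-mixed scalar — at vast molar
excess it equilibrates much faster than any 24 h readout.

Cell motion is an unbiased run-and-tumble walk: constant heading between
exponentially timed re-orientations, reflecting walls.  Because headings
are piecewise constant, first-contact times between any two agents are
closed-form (a quadratic in time), which is what the interaction map
exploits: instead of testing every pair every tick, contacts are predicted
once per motion segment and only re-examined around the predicted window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model_core import ModelParameters

__all__ = [
    "VOXEL_EDGE_UM",
    "WellEnvironment",
    "ContactEvent",
    "diffusion_stability_dt",
    "diffuse_ifng",
    "deposit_ifng",
    "build_interaction_map",
    "resolve_contact",
    "save_field",
    "load_field",
]

#: Spatial resolution of the environment grid (um).
VOXEL_EDGE_UM = 50.0


@dataclass
class WellEnvironment:
    """Voxelized well with an IFN-gamma field and a well-mixed antibody."""

    box_size: tuple[float, float, float]  # um
    ifng_field: np.ndarray  # per-voxel concentration, a.u. / um^3
    ab_conc: float  # molar
    clock: float = 0.0  # hours
    voxel: float = VOXEL_EDGE_UM

    @classmethod
    def empty(cls, box_size: Sequence[float], ab_conc: float = 0.0,
              voxel: float = VOXEL_EDGE_UM) -> "WellEnvironment":
        shape = tuple(max(1, int(round(s / voxel))) for s in box_size)
        box = tuple(n * voxel for n in shape)
        return cls(box_size=box, ifng_field=np.zeros(shape), ab_conc=ab_conc, voxel=voxel)

    @property
    def voxel_volume(self) -> float:
        return self.voxel**3

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.box_size))

    def total_ifng(self) -> float:
        """Total IFN-gamma mass (a.u.) in the well."""
        return float(self.ifng_field.sum() * self.voxel_volume)

    def voxel_index(self, position: np.ndarray) -> tuple[int, ...]:
        idx = []
        for d in range(3):
            if not (0.0 <= position[d] <= self.box_size[d]):
                raise ValueError(
                    f"position {position} outside the box {self.box_size}"
                )
            idx.append(min(int(position[d] // self.voxel), self.ifng_field.shape[d] - 1))
        return tuple(idx)

    def local_ifng(self, position: np.ndarray) -> float:
        return float(self.ifng_field[self.voxel_index(position)])


@dataclass
class ContactEvent:
    """Predicted first contact between two agents moving on straight lines."""

    agent_a: int
    agent_b: int
    predicted_time: float  # absolute hours
    predicted_point: np.ndarray
    exit_time: float = math.inf  # when the pair separates again (absolute hours)


def diffusion_stability_dt(diffusion_coeff: float, voxel: float = VOXEL_EDGE_UM) -> float:
    """Largest stable explicit step: dt <= h^2 / (6 D)."""
    if diffusion_coeff <= 0:
        return math.inf
    return voxel**2 / (6.0 * diffusion_coeff)


def diffuse_ifng(
    field: np.ndarray,
    dt: float,
    diffusion_coeff: float,
    decay_rate: float,
    voxel: float = VOXEL_EDGE_UM,
) -> np.ndarray:
    """One explicit diffusion + decay step on the concentration field.

    7-point stencil with zero-flux boundaries (implemented by edge
    padding, so the discrete Laplacian sees its own value across every
    face), followed by exact exponential decay.  Mass is conserved by the
    diffusion part to floating-point accuracy.
    """
    bound = diffusion_stability_dt(diffusion_coeff, voxel)
    if dt > bound:
        raise ValueError(
            f"dt = {dt} h violates the explicit diffusion stability bound "
            f"dt <= h^2/(6D) = {bound:.4g} h (h = {voxel} um, D = {diffusion_coeff} um^2/h)"
        )
    out = np.asarray(field, dtype=float)
    if diffusion_coeff > 0.0:
        alpha = diffusion_coeff * dt / voxel**2
        padded = np.pad(out, 1, mode="edge")
        lap = (
            padded[:-2, 1:-1, 1:-1] + padded[2:, 1:-1, 1:-1]
            + padded[1:-1, :-2, 1:-1] + padded[1:-1, 2:, 1:-1]
            + padded[1:-1, 1:-1, :-2] + padded[1:-1, 1:-1, 2:]
            - 6.0 * out
        )
        out = out + alpha * lap
    if decay_rate > 0.0:
        out = out * math.exp(-decay_rate * dt)
    return np.maximum(out, 0.0)


def deposit_ifng(
    field: np.ndarray,
    position: np.ndarray,
    amount: float,
    voxel: float = VOXEL_EDGE_UM,
) -> np.ndarray:
    """Deposit a secreted amount into the voxel containing ``position``.

    The concentration of that voxel rises by amount / voxel_volume, so total
    mass increases by exactly ``amount``.  Returns the (mutated) field.
    """
    if amount < 0:
        raise ValueError("amount must be non-negative")
    idx = []
    for d in range(3):
        extent = field.shape[d] * voxel
        if not (0.0 <= position[d] <= extent):
            raise ValueError(f"position {position} outside the box (extent {extent} um in axis {d})")
        idx.append(min(int(position[d] // voxel), field.shape[d] - 1))
    field[tuple(idx)] += amount / voxel**3
    return field


def _pair_contact_window(dp, dv, radius_sum):
    """Entry/exit times of the contact window |dp + dv t| <= R, or None.

    Closed-form roots of the quadratic ||dp + dv t||^2 = R^2.
    """
    c = float(np.dot(dp, dp)) - radius_sum**2
    a = float(np.dot(dv, dv))
    b = 2.0 * float(np.dot(dp, dv))
    if a < 1e-300:
        return (0.0, math.inf) if c <= 0.0 else None
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    t_in = (-b - sq) / (2.0 * a)
    t_out = (-b + sq) / (2.0 * a)
    if t_out < 0.0:
        return None
    return (max(t_in, 0.0), t_out)


def build_interaction_map(
    positions: np.ndarray,
    velocities: np.ndarray,
    radii: np.ndarray,
    horizon: float,
    now: float = 0.0,
    pairs: Optional[np.ndarray] = None,
) -> List[ContactEvent]:
    """Predict all pairwise surface contacts within ``horizon`` hours.

    Assumes straight-line motion at the current headings (valid until the
    next tumble or wall reflection, after which the affected agents'
    predictions must be rebuilt).  Agents already in contact get
    ``predicted_time = now``.  ``pairs`` optionally restricts the candidate
    pair list (rows of index pairs); by default all pairs are examined.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(positions)
    if pairs is None:
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.column_stack([ii, jj])
    events: List[ContactEvent] = []
    for i, j in pairs:
        window = _pair_contact_window(
            positions[i] - positions[j],
            velocities[i] - velocities[j],
            radii[i] + radii[j],
        )
        if window is None or window[0] > horizon:
            continue
        t_in, t_out = window
        point = 0.5 * (
            positions[i] + velocities[i] * t_in + positions[j] + velocities[j] * t_in
        )
        events.append(ContactEvent(int(i), int(j), now + t_in, point, now + t_out))
    events.sort(key=lambda e: (e.predicted_time, e.agent_a, e.agent_b))
    return events


def save_field(env: WellEnvironment, path) -> None:
    """Export the IFN-gamma field as a text grid with a header.

    Header lines carry the grid dimensions, voxel edge (um), units and the
    simulation clock; data follow as one value per line in C order.
    """
    header = (
        f"dims {env.ifng_field.shape[0]} {env.ifng_field.shape[1]} {env.ifng_field.shape[2]}\n"
        f"voxel_um {env.voxel}\n"
        f"units a.u./um^3\n"
        f"clock_h {env.clock}"
    )
    np.savetxt(path, env.ifng_field.reshape(-1), header=header)


def load_field(path) -> WellEnvironment:
    """Read a field written by :func:`save_field`."""
    import re

    with open(path) as fh:
        text = fh.read()
    m = re.search(r"dims (\d+) (\d+) (\d+)", text)
    v = re.search(r"voxel_um ([\d.eE+-]+)", text)
    c = re.search(r"clock_h ([\d.eE+-]+)", text)
    if m is None or v is None:
        raise ValueError(f"{path}: missing grid header")
    shape = tuple(int(g) for g in m.groups())
    voxel = float(v.group(1))
    values = np.loadtxt(path).reshape(shape)
    env = WellEnvironment(
        box_size=tuple(s * voxel for s in shape),
        ifng_field=values,
        ab_conc=0.0,
        clock=float(c.group(1)) if c else 0.0,
        voxel=voxel,
    )
    return env


def resolve_contact(tcell, monocyte, params: ModelParameters, rng: np.random.Generator) -> str:
    """Outcome of a completed T-cell scan of a monocyte.

    Returns "synapse" with probability ``p_synapse``, else "disengage".
    A dead monocyte always disengages.
    """
    if not monocyte.alive:
        return "disengage"
    return "synapse" if rng.random() < params.p_synapse else "disengage"
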