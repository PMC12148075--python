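"""Per-agent state machines for T cells and monocytes.

T cell: three occupancy signals in [0, 1] — anti-CD3 stimulation (f_acd3),
CD28/CD80 co-stimulation (f_cost, contact-dependent) and PD-1/PD-L1
inhibition (f_inh, contact-dependent and relieved by antibody blockade) —
combine into a single drive

    acoeff = -k_inh * f_inh + (1 + k_cost * f_cost) * (k_acd3 * f_acd3)

which sets a hidden activation level

    act = clamp_[0,1]( (1 + tanh(beta * (acoeff - theta))) / 2 + inhib_general )

Activation drives PD-1 production (internal pool, expressed on the surface
after a stochastic translocation delay) and IFN-gamma secretion.  A slow
"general inhibition" pool relaxes toward a (negative) resting value,
standing in for the unmeasured collective exhaustion mechanisms that wind
activation down late in the assay.

Monocyte: no hidden activation.  PD-L1 and CD80 production is driven by the
locally sensed IFN-gamma concentration through a saturating response
``c / (c + ifng_half_sat)``, with the same produce-then-translocate scheme.
Monocyte death is a constant hazard, independent of IFN-gamma.

Occupancies use single-site saturating (Hill-1) forms — the minimal choice
consistent with saturating-binding semantics.  Antibody blockade is
equilibrium competitive occupancy: the unblocked PD-L1 fraction is
``kd_ab / (kd_ab + ab_conc)``, valid while the soluble antibody is in molar
excess over receptors (it is, at simulated cell numbers, down to the lowest
doses on the protocol grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .model_core import ModelParameters

__all__ = [
    "TCellState",
    "MonocyteState",
    "unblocked_fraction",
    "hill",
    "compute_occupancies",
    "compute_activation",
    "sample_transloc_delay",
    "step_tcell",
    "step_monocyte",
]

#: Explicit-Euler stability guard for the first-order pool ODEs: dt must
#: resolve the fastest decay rate with margin.
_ODE_STABILITY_FACTOR = 0.5


@dataclass
class TCellState:
    """Mutable state of one T-cell agent."""

    subset: str = "CD4"  # CD4 | CD8, used for initialization and readout only
    pd1_surface: float = 0.0
    pd1_baseline: Optional[float] = None  # constitutive level; defaults to initial surface
    pd1_internal: float = 0.0
    act: float = 0.0
    acoeff: float = 0.0
    inhib_general: float = 0.0
    f_acd3: float = 0.0
    f_cost: float = 0.0
    f_inh: float = 0.0
    ifng_pending: float = 0.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contact: str = "none"  # none | scanning | synapse
    partner: Optional[int] = None
    transloc_queue: List[Tuple[float, float]] = field(default_factory=list)  # (amount, due_time)

    def __post_init__(self) -> None:
        if self.pd1_baseline is None:
            self.pd1_baseline = self.pd1_surface


@dataclass
class MonocyteState:
    """Mutable state of one monocyte agent."""

    pdl1_surface: float = 0.0
    pdl1_internal: float = 0.0
    cd80_surface: float = 0.0
    cd80_internal: float = 0.0
    alive: bool = True
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # (receptor, amount, due_time) with receptor in {"pdl1", "cd80"}
    transloc_queue: List[Tuple[str, float, float]] = field(default_factory=list)


def unblocked_fraction(ab_conc, kd_ab):
    """Fraction of PD-L1 not occupied by antibody at equilibrium.

    Single-site competitive occupancy with no antibody depletion:
    ``kd / (kd + [Ab])`` — 1 with no antibody, 0.5 at [Ab] = Kd.
    """
    return kd_ab / (kd_ab + np.asarray(ab_conc, dtype=float))


def hill(x, k):
    """Hill-1 saturation ``x / (x + k)``, safe at x = k = 0."""
    x = np.asarray(x, dtype=float)
    return np.where(x + k > 0, x / np.where(x + k > 0, x + k, 1.0), 0.0)


def compute_occupancies(
    tcell: TCellState,
    partner: Optional[MonocyteState],
    anti_cd3: bool,
    ab_conc: float,
    params: ModelParameters,
) -> tuple[float, float, float]:
    """Occupancy signals (f_acd3, f_cost, f_inh), each in [0, 1].

    Contact-dependent signals are zero without a live synapse partner.
    f_inh saturates in the product of the T cell's surface PD-1 and the
    partner's *unblocked* surface PD-L1.
    """
    f_acd3 = float(hill(params.acd3_dose, params.kd_cd3_acd3)) if anti_cd3 else 0.0
    if partner is None or not partner.alive:
        return f_acd3, 0.0, 0.0
    f_cost = float(hill(partner.cd80_surface, params.kd_cd28_cd80))
    free_pdl1 = partner.pdl1_surface * float(unblocked_fraction(ab_conc, params.kd_ab))
    f_inh = float(hill(tcell.pd1_surface * free_pdl1, params.kd_pd1_pdl1))
    return f_acd3, f_cost, f_inh


def compute_activation(f_inh, f_cost, f_acd3, inhib_general, params: ModelParameters):
    """Combined drive and clamped hidden activation.

    Vectorized: scalar or array inputs are both accepted.
    """
    acoeff = -params.k_inh * np.asarray(f_inh, dtype=float) + (
        1.0 + params.k_cost * np.asarray(f_cost, dtype=float)
    ) * (params.k_acd3 * np.asarray(f_acd3, dtype=float))
    act = (1.0 + np.tanh(params.beta * (acoeff - params.theta))) / 2.0 + inhib_general
    act = np.clip(act, 0.0, 1.0)
    if np.ndim(acoeff) == 0:
        return float(acoeff), float(act)
    return acoeff, act


def sample_transloc_delay(mean: float, cv: float, rng: np.random.Generator, size=None):
    """Stochastic internal->surface translocation delay (hours).

    Log-normal parameterized by its mean and coefficient of variation; a CV
    of 0 degenerates to a fixed delay.
    """
    if cv <= 0.0:
        return mean if size is None else np.full(size, mean)
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def _check_dt(dt: float, params: ModelParameters) -> None:
    fastest = max(params.pd1_decay_rate, params.ifng_decay_rate, 1e-12)
    if dt > _ODE_STABILITY_FACTOR / fastest:
        raise ValueError(
            f"dt = {dt} h exceeds the explicit-Euler stability bound "
            f"{_ODE_STABILITY_FACTOR / fastest:.4g} h for decay rate {fastest}/h"
        )


def step_tcell(
    tcell: TCellState,
    dt: float,
    now: float,
    params: ModelParameters,
    rng: np.random.Generator,
) -> tuple[TCellState, float]:
    """Advance one T cell by dt hours; returns (updated cell, IFN-gamma emitted).

    The caller is expected to have refreshed ``f_acd3/f_cost/f_inh`` (via
    :func:`compute_occupancies`) for the current contact situation.  The
    activation level is recomputed, a PD-1 production quantum proportional
    to activation is queued for delayed surface expression, due quanta are
    moved internal -> surface, surface PD-1 turns over at ``pd1_decay_rate``
    and IFN-gamma ``secretion_rate * act * dt`` is emitted.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_dt(dt, params)

    # General inhibition relaxes toward its resting value.
    tcell.inhib_general += -params.k_general * (tcell.inhib_general - params.inhib_rest) * dt

    tcell.acoeff, tcell.act = compute_activation(
        tcell.f_inh, tcell.f_cost, tcell.f_acd3, tcell.inhib_general, params
    )

    quantum = params.pd1_prod_rate * tcell.act * dt
    if quantum > 0.0:
        tcell.pd1_internal += quantum
        due = now + sample_transloc_delay(params.pd1_transloc_mean, params.pd1_transloc_cv, rng)
        tcell.transloc_queue.append((quantum, float(due)))

    t_end = now + dt
    still_queued: List[Tuple[float, float]] = []
    for amount, due in tcell.transloc_queue:
        if due <= t_end:
            moved = min(amount, tcell.pd1_internal)
            tcell.pd1_internal -= moved
            tcell.pd1_surface += moved
        else:
            still_queued.append((amount, due))
    tcell.transloc_queue = still_queued

    # Only activation-induced surface PD-1 turns over; the constitutive
    # baseline is homeostatically maintained.
    induced = max(tcell.pd1_surface - tcell.pd1_baseline, 0.0)
    tcell.pd1_surface = tcell.pd1_baseline + induced * (1.0 - params.pd1_decay_rate * dt)
    tcell.pd1_internal = max(tcell.pd1_internal, 0.0)

    ifng_emitted = params.ifng_secretion_rate * tcell.act * dt
    return tcell, ifng_emitted


def step_monocyte(
    mono: MonocyteState,
    local_ifng: float,
    dt: float,
    now: float,
    params: ModelParameters,
    rng: np.random.Generator,
) -> MonocyteState:
    """Advance one monocyte by dt hours.

    The normalized IFN-gamma response ``drive = c / (c + half_sat)`` scales
    inducible PD-L1/CD80 production on top of a small constitutive term;
    produced quanta surface after a stochastic delay.  Death is sampled with
    probability ``1 - exp(-hazard * dt)``, independent of IFN-gamma.
    """
    if local_ifng < 0:
        raise ValueError("local_ifng must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not mono.alive:
        return mono

    drive = float(hill(local_ifng, params.ifng_half_sat))
    for receptor, rate, basal in (
        ("pdl1", params.pdl1_prod_rate, params.pdl1_basal_rate),
        ("cd80", params.cd80_prod_rate, params.cd80_basal_rate),
    ):
        quantum = (rate * drive + basal) * dt
        if quantum > 0.0:
            if receptor == "pdl1":
                mono.pdl1_internal += quantum
            else:
                mono.cd80_internal += quantum
            due = now + sample_transloc_delay(
                params.mono_transloc_mean, params.mono_transloc_cv, rng
            )
            mono.transloc_queue.append((receptor, quantum, float(due)))

    t_end = now + dt
    still_queued: List[Tuple[str, float, float]] = []
    for receptor, amount, due in mono.transloc_queue:
        if due <= t_end:
            if receptor == "pdl1":
                moved = min(amount, mono.pdl1_internal)
                mono.pdl1_internal -= moved
                mono.pdl1_surface += moved
            else:
                moved = min(amount, mono.cd80_internal)
                mono.cd80_internal -= moved
                mono.cd80_surface += moved
        else:
            still_queued.append((receptor, amount, due))
    mono.transloc_queue = still_queued

    if rng.random() < -np.expm1(-params.mono_death_hazard * dt):
        mono.alive = False
    return mono
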