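"""Domain types, parameter registry, and donor-specific population initialization.

The simulated assay is an autologous mixed-lymphocyte reaction (MLR): memory
T cells co-cultured with monocytes from the same donor, stimulated with
soluble anti-CD3, and titrated with an anti-PD-L1 blocking antibody.  A well
is represented at reduced scale (``volume_scale``) with cell densities
matching the 125,000 monocytes + 75,000 T cells in 200 µl of the bench
protocol.

Per-donor heterogeneity enters through the baseline immunophenotype: the
fraction of PD-1-positive memory T cells, the geometric mean of PD-1
fluorescence, and the analogous PD-L1 statistics on monocytes.  Baseline
receptor levels per agent are drawn from a log-normal distribution pinned
down by exactly those two statistics (geometric mean + fraction above a
gate), which is the classical model for flow-cytometry intensities.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = [
    "DonorPhenotype",
    "ModelParameters",
    "SimulationConfig",
    "DegenerateDistributionError",
    "estimate_pd1_distribution",
    "initialize_population",
    "FULL_WELL_VOLUME_UL",
    "FULL_WELL_BOTTOM_AREA_UM2",
]

#: Bench-scale well: 200 µl medium over a flat-bottom 96-well (~0.32 cm²).
FULL_WELL_VOLUME_UL = 200.0
FULL_WELL_BOTTOM_AREA_UM2 = 3.2e7

#: Log-normal dispersion is clamped to this range to avoid degenerate tails.
SIGMA_BOUNDS = (0.05, 3.0)
#: Dispersion used when the gate sits exactly on the geometric mean
#: (the tail fraction then carries no information about sigma).
SIGMA_DEFAULT = 0.8


class DegenerateDistributionError(ValueError):
    """Raised when (geo_mean, pct_positive, gate) admit no log-normal solution."""


class DonorPhenotype(BaseModel):
    """Baseline flow-cytometry summary of one donor.

    Percentages are "% of cells above the positivity gate"; geometric means
    are fluorescence-intensity surrogates for per-cell receptor density
    (arbitrary units).
    """

    model_config = ConfigDict(extra="forbid")

    donor_id: str
    pct_pd1_cd4: float = Field(ge=0.0, le=100.0)
    pct_pd1_cd8: float = Field(ge=0.0, le=100.0)
    geo_mean_pd1: float = Field(gt=0.0)
    pct_pdl1_mono: float = Field(ge=0.0, le=100.0)
    geo_mean_pdl1: float = Field(gt=0.0)
    mlr_days: int = Field(default=4, ge=1, le=7)


class ModelParameters(BaseModel):
    """All tunable rates and constants of the cell state machines.

    Defaults were calibrated once against the qualitative kinetics of the
    bench assay (PD-1 peak near 72 h, monocyte PD-L1 positivity >= 80 % by
    24 h, IFN-gamma peak at 72-96 h) and are documented in docs/methods.md.
    """

    model_config = ConfigDict(extra="forbid")

    # --- T-cell activation law -------------------------------------------
    k_inh: float = Field(default=2.2, ge=0.0, description="weight of PD-1/PD-L1 inhibition")
    k_cost: float = Field(default=0.8, ge=0.0, description="weight of CD28/CD80 co-stimulation")
    k_acd3: float = Field(default=1.0, ge=0.0, description="weight of anti-CD3 stimulation")
    beta: float = Field(default=2.2, gt=0.0, description="activation steepness")
    theta: float = Field(default=0.5, description="activation threshold on the combined drive")
    k_general: float = Field(default=0.025, ge=0.0, description="relaxation rate of the general-inhibition pool (1/h)")
    inhib_rest: float = Field(default=-0.6, description="resting value the general-inhibition pool relaxes toward")

    # --- Binding constants ------------------------------------------------
    kd_ab: float = Field(default=1.0e-11, gt=0.0, description="antibody/PD-L1 dissociation constant (M)")
    kd_pd1_pdl1: float = Field(default=120.0, gt=0.0, description="half-saturation of the PD-1*PD-L1 occupancy product (a.u.^2)")
    kd_cd28_cd80: float = Field(default=12.0, gt=0.0, description="half-saturation of CD80-driven co-stimulation (a.u.)")
    kd_cd3_acd3: float = Field(default=0.25, ge=0.0, description="anti-CD3 occupancy constant relative to the applied dose")

    # --- T-cell PD-1 / IFN-gamma dynamics ---------------------------------
    pd1_prod_rate: float = Field(default=0.7, ge=0.0, description="PD-1 production per unit activation (a.u./h)")
    pd1_decay_rate: float = Field(default=0.04, ge=0.0, description="surface PD-1 turnover (1/h)")
    pd1_transloc_mean: float = Field(default=24.0, gt=0.0, description="mean internal->surface translocation delay (h)")
    pd1_transloc_cv: float = Field(default=0.5, ge=0.0, description="CV of the translocation delay")
    ifng_secretion_rate: float = Field(default=1.0, ge=0.0, description="IFN-gamma secretion per unit activation (a.u./h)")
    ifng_decay_rate: float = Field(default=0.008, ge=0.0, description="first-order IFN-gamma decay in medium (1/h)")

    # --- Monocyte PD-L1 / CD80 dynamics -----------------------------------
    pdl1_prod_rate: float = Field(default=1.1, ge=0.0, description="IFN-gamma-driven PD-L1 production (a.u./h at full drive)")
    pdl1_basal_rate: float = Field(default=0.02, ge=0.0, description="constitutive PD-L1 production (a.u./h)")
    cd80_prod_rate: float = Field(default=0.6, ge=0.0, description="IFN-gamma-driven CD80 production (a.u./h at full drive)")
    cd80_basal_rate: float = Field(default=0.02, ge=0.0, description="constitutive CD80 production (a.u./h)")
    mono_transloc_mean: float = Field(default=0.5, gt=0.0, description="mean monocyte translocation delay (h)")
    mono_transloc_cv: float = Field(default=0.5, ge=0.0, description="CV of the monocyte translocation delay")
    ifng_half_sat: float = Field(default=6.0e-5, gt=0.0, description="IFN-gamma concentration at half-maximal monocyte response (a.u./um^3)")
    mono_death_hazard: float = Field(default=0.02, ge=0.0, description="monocyte death hazard, IFN-gamma independent (1/h)")
    cd80_baseline_geo_mean: float = Field(default=8.0, gt=0.0, description="baseline CD80 geometric mean (a.u.)")
    cd80_baseline_sigma: float = Field(default=0.4, ge=0.0, description="baseline CD80 log-normal dispersion")

    # --- Environment and motion -------------------------------------------
    diffusion_coeff: float = Field(default=1.1e4, ge=0.0, description="IFN-gamma diffusion coefficient (um^2/h)")
    motion_speed: float = Field(default=360.0, ge=0.0, description="cell crawling speed (um/h)")
    tumble_rate: float = Field(default=2.0, ge=0.0, description="rate of random re-orientation (1/h)")
    tcell_radius: float = Field(default=4.0, gt=0.0, description="T-cell radius (um)")
    mono_radius: float = Field(default=8.0, gt=0.0, description="monocyte radius (um)")
    settle_height: float = Field(default=40.0, gt=0.0, description="height of the settled cell layer above the well floor (um)")

    # --- Contact state machine --------------------------------------------
    p_synapse: float = Field(default=0.5, ge=0.0, le=1.0, description="probability a scan converts into a synapse")
    scan_duration_h: float = Field(default=0.1, gt=0.0, description="duration of the scanning phase (h)")
    synapse_duration_h: float = Field(default=1.0, gt=0.0, description="lifetime of an immunological synapse (h)")

    # --- Integration steps --------------------------------------------------
    dt_fast: float = Field(default=0.02, gt=0.0, description="fast step: diffusion substepping (h)")
    dt_slow: float = Field(default=0.1, gt=0.0, description="slow step: motion, contacts, agent ODEs (h)")

    # --- Readout gates -------------------------------------------------------
    pd1_pos_threshold: float = Field(default=10.0, gt=0.0, description="surface PD-1 gate for the %PD-1+ readout (a.u.)")
    pdl1_pos_threshold: float = Field(default=10.0, gt=0.0, description="surface PD-L1 gate for the %PD-L1+ readout (a.u.)")

    # --- Anti-CD3 dosing ------------------------------------------------------
    acd3_dose: float = Field(default=1.0, ge=0.0, description="applied anti-CD3 amount, in units of its occupancy constant scale")

    @model_validator(mode="after")
    def _check_steps(self) -> "ModelParameters":
        if self.dt_fast > self.dt_slow:
            raise ValueError("dt_fast must not exceed dt_slow")
        return self


class SimulationConfig(BaseModel):
    """Complete description of one in silico MLR well."""

    model_config = ConfigDict(extra="forbid")

    donor: DonorPhenotype
    params: ModelParameters = Field(default_factory=ModelParameters)
    n_tcells: int = Field(default=750, ge=1)
    n_monocytes: int = Field(default=1250, ge=1)
    volume_scale: float = Field(default=0.01, gt=0.0, le=1.0)
    anti_cd3_present: bool = True
    anti_pdl1_conc: float = Field(default=0.0, ge=0.0, description="molar anti-PD-L1 concentration; 0 = IgG/control")
    duration_h: float = Field(default=96.0, gt=0.0)
    readout_times_h: list[float] = Field(default_factory=lambda: [24.0, 48.0, 72.0, 96.0])
    seed: int = Field(default=0, ge=0)
    n_replicates: int = Field(default=1, ge=1)
    settled: bool = Field(default=True, description="cells settled on the well floor (2D motion layer)")
    tcell_cd4_fraction: float = Field(default=0.6, ge=0.0, le=1.0)
    contact_mode: str = Field(default="naive", pattern="^(naive|map)$")

    @model_validator(mode="after")
    def _check_readouts(self) -> "SimulationConfig":
        for t in self.readout_times_h:
            if not (0.0 <= t <= self.duration_h):
                raise ValueError(f"readout time {t} h outside [0, {self.duration_h}] h")
        return self


def estimate_pd1_distribution(
    geo_mean: float,
    pct_positive: float,
    gate_threshold: float,
    n_agents: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample per-agent baseline receptor levels from donor flow statistics.

    Levels are log-normal with geometric mean ``geo_mean`` and dispersion
    ``sigma`` chosen so the expected fraction above ``gate_threshold`` equals
    ``pct_positive``/100:  ``sigma = ln(gate/geo_mean) / z_(1 - pct/100)``.

    When the gate coincides with the geometric mean (or pct = 50) the tail
    fraction carries no information and a default dispersion is used.  A
    pct of exactly 0 or 100 pins sigma at 0; it is clamped to the lower
    dispersion bound, which reproduces the requested tail to within
    sampling error.  A combination with no solution (e.g. pct < 50 but the
    gate is *below* the geometric mean) raises
    :class:`DegenerateDistributionError`.
    """
    if geo_mean <= 0:
        raise ValueError("geo_mean must be positive")
    if not (0.0 <= pct_positive <= 100.0):
        raise ValueError("pct_positive must be in [0, 100]")
    if gate_threshold <= 0:
        raise ValueError("gate_threshold must be positive")
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu = math.log(geo_mean)
    log_ratio = math.log(gate_threshold / geo_mean)
    p = pct_positive / 100.0

    if abs(log_ratio) < 1e-12 or abs(p - 0.5) < 1e-12:
        # Gate on the geometric mean: any sigma yields a 50 % tail.
        sigma = SIGMA_DEFAULT
    elif p <= 0.0 or p >= 1.0:
        # Zero or full positivity: sigma -> 0 works only if the gate is on
        # the correct side of the geometric mean.
        wrong_side = (p <= 0.0 and gate_threshold < geo_mean) or (
            p >= 1.0 and gate_threshold > geo_mean
        )
        if wrong_side:
            raise DegenerateDistributionError(
                "pct_positive of 0/100 is inconsistent with the gate lying on "
                "this side of the geometric mean; adjust the gate or report a "
                "non-degenerate percentage"
            )
        sigma = SIGMA_BOUNDS[0]
    else:
        z = stats.norm.ppf(1.0 - p)  # upper-tail quantile
        sigma = log_ratio / z
        if sigma <= 0:
            raise DegenerateDistributionError(
                f"no log-normal with geometric mean {geo_mean} puts "
                f"{pct_positive}% of mass above {gate_threshold}; the gate "
                "lies on the wrong side of the geometric mean for that tail"
            )
    sigma = float(np.clip(sigma, *SIGMA_BOUNDS))
    return np.exp(rng.normal(mu, sigma, size=n_agents))


def _box_dimensions(volume_scale: float, voxel: float = 50.0) -> tuple[float, float, float]:
    """Scaled-well box, preserving the bench bottom-area-to-volume ratio.

    The footprint scales with ``volume_scale`` so that, once cells settle,
    their areal density matches the bench well; the depth then follows from
    the scaled volume.  Both are rounded to whole voxels.
    """
    volume_um3 = FULL_WELL_VOLUME_UL * 1e9 * volume_scale
    area = FULL_WELL_BOTTOM_AREA_UM2 * volume_scale
    side = max(voxel, round(math.sqrt(area) / voxel) * voxel)
    depth = max(voxel, round(volume_um3 / side**2 / voxel) * voxel)
    return (side, side, depth)


def initialize_population(config: SimulationConfig):
    """Build donor-specific agent populations and an empty well.

    T-cell agents receive baseline surface PD-1 sampled from the donor's
    (geometric mean, % positive) statistics, stratified by CD4/CD8 subset;
    monocytes receive baseline PD-L1 analogously, plus a baseline CD80 pool.
    Agents are placed uniformly at random (within the settled layer when
    ``config.settled``).  The IFN-gamma field starts at zero and the
    antibody concentration is taken from the config.

    Returns ``(tcells, monocytes, env)`` where the first two are lists of
    :class:`~mlrabm.agent_dynamics.TCellState` /
    :class:`~mlrabm.agent_dynamics.MonocyteState` and ``env`` is a
    :class:`~mlrabm.environment.WellEnvironment`.
    """
    from .agent_dynamics import MonocyteState, TCellState
    from .environment import WellEnvironment

    p = config.params
    rng = np.random.default_rng(config.seed)
    box = _box_dimensions(config.volume_scale)

    n_total = config.n_tcells + config.n_monocytes
    if config.settled:
        layer_volume = box[0] * box[1] * p.settle_height
    else:
        layer_volume = box[0] * box[1] * box[2]
    cell_volume = (4.0 / 3.0) * math.pi * p.mono_radius**3
    if n_total * cell_volume > 0.5 * layer_volume:
        raise ValueError(
            f"{n_total} agents exceed the packing capacity of the "
            f"{'settled layer' if config.settled else 'well'} "
            f"({layer_volume:.3g} um^3); increase volume_scale or reduce counts"
        )

    n_cd4 = int(round(config.n_tcells * config.tcell_cd4_fraction))
    pd1_cd4 = estimate_pd1_distribution(
        config.donor.geo_mean_pd1, config.donor.pct_pd1_cd4,
        p.pd1_pos_threshold, max(n_cd4, 1), rng,
    )[:n_cd4]
    n_cd8 = config.n_tcells - n_cd4
    pd1_cd8 = estimate_pd1_distribution(
        config.donor.geo_mean_pd1, config.donor.pct_pd1_cd8,
        p.pd1_pos_threshold, max(n_cd8, 1), rng,
    )[:n_cd8]

    pdl1 = estimate_pd1_distribution(
        config.donor.geo_mean_pdl1, config.donor.pct_pdl1_mono,
        p.pdl1_pos_threshold, config.n_monocytes, rng,
    )
    cd80 = np.exp(rng.normal(math.log(p.cd80_baseline_geo_mean),
                             max(p.cd80_baseline_sigma, 1e-12),
                             size=config.n_monocytes))

    def _positions(n: int) -> np.ndarray:
        pos = np.empty((n, 3))
        pos[:, 0] = rng.uniform(0.0, box[0], n)
        pos[:, 1] = rng.uniform(0.0, box[1], n)
        zmax = p.settle_height if config.settled else box[2]
        pos[:, 2] = rng.uniform(0.0, zmax, n)
        return pos

    tpos = _positions(config.n_tcells)
    mpos = _positions(config.n_monocytes)

    tcells = []
    for i in range(config.n_tcells):
        subset = "CD4" if i < n_cd4 else "CD8"
        baseline = pd1_cd4[i] if i < n_cd4 else pd1_cd8[i - n_cd4]
        tcells.append(TCellState(subset=subset, pd1_surface=float(baseline),
                                 position=tpos[i].copy()))
    monocytes = [
        MonocyteState(pdl1_surface=float(pdl1[i]), cd80_surface=float(cd80[i]),
                      position=mpos[i].copy())
        for i in range(config.n_monocytes)
    ]

    env = WellEnvironment.empty(box_size=box, ab_conc=config.anti_pdl1_conc)
    return tcells, monocytes, env
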