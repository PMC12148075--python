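"""The in silico MLR protocol: run one well, run a dose titration.

The engine advances all agents on a fixed slow tick (``dt_slow``, default
6 min): motion and the contact state machine (free -> scanning -> synapse),
the activation/receptor dynamics of every T cell and monocyte, IFN-gamma
deposition, and then diffusion sub-stepped at ``dt_fast``.  Agent state is
held in flat NumPy arrays (structure-of-arrays) so a 2,000-agent, 4-day
well runs in seconds; the per-agent functions in
:mod:`mlrabm.agent_dynamics` define the same update laws on single agents.

Randomness is split into independent streams (motion, contact outcomes,
translocation delays, monocyte death), all derived from the config seed.
Streams whose draw counts do not depend on the treatment (motion, death,
translocation) consume identically across antibody doses, so replicate
runs at different doses share their random numbers: dose effects are then
paired comparisons, which sharpens the emergent dose-response curve the
same way paired wells do on the bench.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .agent_dynamics import compute_activation, hill, unblocked_fraction
from .environment import diffuse_ifng, diffusion_stability_dt
from .model_core import DonorPhenotype, SimulationConfig, initialize_population

__all__ = [
    "ReadoutFrame",
    "DoseResponseTable",
    "DEFAULT_DOSE_GRID",
    "run_mlr",
    "run_dose_response",
    "replicate_seed",
]

#: Protocol titration: decade steps over the bench range 1e-13 .. 1e-7 M.
DEFAULT_DOSE_GRID: tuple[float, ...] = tuple(10.0 ** e for e in range(-13, -6))

#: Condition labels used in dose-response tables.
COND_NO_ABS = "no_abs"
COND_ACD3_ONLY = "acd3_only"

_FREE, _SCANNING, _SYNAPSE = 0, 1, 2
#: Cool-down after a disengaged scan before the same T cell scans again (h).
_SCAN_COOLDOWN_H = 0.2


@dataclass
class ReadoutFrame:
    """Well-level readouts at one time point."""

    time_h: float
    pct_pd1_cd4: float
    pct_pd1_cd8: float
    ifng_total: float  # a.u., total mass in the well
    ifng_conc_per_ml: float  # a.u./ml, scale-invariant across volume_scale
    pct_pdl1_mono: float  # among live monocytes
    n_live_mono: int


@dataclass
class DoseResponseTable:
    """Tidy per-(condition, replicate) final readouts of a titration."""

    donor_id: str
    df: pd.DataFrame

    COLUMNS = [
        "donor_id", "condition", "dose_M", "replicate", "time_h",
        "pct_pd1_cd4", "pct_pd1_cd8", "ifng", "pct_pdl1_mono",
    ]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseTable":
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns: {missing}")
        donor_ids = df["donor_id"].unique()
        return cls(donor_id=str(donor_ids[0]) if len(donor_ids) else "", df=df)


class SimulationDiverged(RuntimeError):
    """Non-finite agent state encountered during a run."""


class _Engine:
    """Vectorized well simulation (internal)."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        p = config.params
        self.p = p
        tcells, monocytes, env = initialize_population(config)
        self.env = env
        self.nt = len(tcells)
        self.nm = len(monocytes)
        self.dt = p.dt_slow

        stab = diffusion_stability_dt(p.diffusion_coeff, env.voxel)
        if p.dt_fast > stab:
            raise ValueError(
                f"dt_fast = {p.dt_fast} h violates the diffusion stability bound "
                f"h^2/(6D) = {stab:.4g} h; lower dt_fast or diffusion_coeff"
            )
        self.n_sub = max(1, math.ceil(self.dt / p.dt_fast))
        self.sub_dt = self.dt / self.n_sub

        # --- T-cell arrays -------------------------------------------------
        self.subset_cd4 = np.array([t.subset == "CD4" for t in tcells])
        self.pd1_base = np.array([t.pd1_surface for t in tcells])
        self.pd1_surf = self.pd1_base.copy()
        self.pd1_int = np.zeros(self.nt)
        self.inhib = np.zeros(self.nt)
        self.act = np.zeros(self.nt)
        self.f_cost = np.zeros(self.nt)
        self.f_inh = np.zeros(self.nt)
        self.tpos = np.array([t.position for t in tcells])
        self.tmode = np.zeros(self.nt, dtype=np.int8)
        self.tpartner = np.full(self.nt, -1, dtype=np.int64)
        self.phase_end = np.zeros(self.nt)
        self.cooldown = np.zeros(self.nt)

        # --- Monocyte arrays ----------------------------------------------
        self.pdl1_surf = np.array([m.pdl1_surface for m in monocytes])
        self.pdl1_int = np.zeros(self.nm)
        self.cd80_surf = np.array([m.cd80_surface for m in monocytes])
        self.cd80_int = np.zeros(self.nm)
        self.alive = np.ones(self.nm, dtype=bool)
        self.mpos = np.array([m.position for m in monocytes])
        self.engaged_by = np.full(self.nm, -1, dtype=np.int64)

        # --- RNG streams ----------------------------------------------------
        ss = np.random.SeedSequence([config.seed, 0x5EED])
        (s_motion, s_contact, s_death, s_tr_t, s_tr_m) = ss.spawn(5)
        self.rng_motion = np.random.default_rng(s_motion)
        self.rng_contact = np.random.default_rng(s_contact)
        self.rng_death = np.random.default_rng(s_death)
        self.rng_tr_t = np.random.default_rng(s_tr_t)
        self.rng_tr_m = np.random.default_rng(s_tr_m)

        # --- Motion state ----------------------------------------------------
        self.theading = self._unit_headings(self.nt, self.rng_motion)
        self.mheading = self._unit_headings(self.nm, self.rng_motion)
        rate = max(p.tumble_rate, 1e-9)
        self.t_next_tumble = self.rng_motion.exponential(1.0 / rate, self.nt)
        self.m_next_tumble = self.rng_motion.exponential(1.0 / rate, self.nm)

        # --- Translocation ring buffers (tick-resolution delay queues) -------
        def ring_len(mean, cv):
            return max(2, math.ceil(mean * (1.0 + 6.0 * cv) / self.dt) + 1)

        self.Ht = ring_len(p.pd1_transloc_mean, p.pd1_transloc_cv)
        self.Hm = ring_len(p.mono_transloc_mean, p.mono_transloc_cv)
        self.ring_t = np.zeros((self.nt, self.Ht))
        self.ring_pdl1 = np.zeros((self.nm, self.Hm))
        self.ring_cd80 = np.zeros((self.nm, self.Hm))

        self.f_acd3 = (
            float(hill(p.acd3_dose, p.kd_cd3_acd3)) if config.anti_cd3_present else 0.0
        )
        self.unblocked = float(unblocked_fraction(config.anti_pdl1_conc, p.kd_ab))
        self.contact_radius = p.tcell_radius + p.mono_radius
        self.tick = 0

        # Interaction-map state (built lazily in "map" mode).
        self._map_enter: Optional[np.ndarray] = None
        self._map_exit: Optional[np.ndarray] = None

        # Log-normal delay parameters, precomputed.
        self._tr_t_params = self._lognorm_params(p.pd1_transloc_mean, p.pd1_transloc_cv)
        self._tr_m_params = self._lognorm_params(p.mono_transloc_mean, p.mono_transloc_cv)

    # ------------------------------------------------------------------ utils
    def _unit_headings(self, n: int, rng: np.random.Generator) -> np.ndarray:
        h = rng.standard_normal((n, 3))
        if self.config.settled:
            h[:, 2] = 0.0
        norms = np.linalg.norm(h, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return h / norms

    @staticmethod
    def _lognorm_params(mean: float, cv: float):
        if cv <= 0:
            return None
        s2 = math.log1p(cv * cv)
        return math.log(mean) - 0.5 * s2, math.sqrt(s2)

    def _sample_delays(self, rng, params, mean, size):
        if params is None:
            return np.full(size, mean)
        mu, sig = params
        return rng.lognormal(mu, sig, size=size)

    def _delay_ticks(self, delays, horizon):
        ticks = np.ceil(delays / self.dt).astype(np.int64)
        return np.clip(ticks, 1, horizon - 1)

    @property
    def now(self) -> float:
        return self.tick * self.dt

    # -------------------------------------------------------------- mechanics
    def _velocities(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        tv = self.theading * p.motion_speed
        tv[self.tmode != _FREE] = 0.0
        mv = self.mheading * p.motion_speed
        mv[(self.engaged_by >= 0) | ~self.alive] = 0.0
        return tv, mv

    def _release(self, t_idx: np.ndarray, with_cooldown: bool) -> None:
        if len(t_idx) == 0:
            return
        partners = self.tpartner[t_idx]
        valid = partners >= 0
        self.engaged_by[partners[valid]] = -1
        self.tmode[t_idx] = _FREE
        self.tpartner[t_idx] = -1
        self.f_cost[t_idx] = 0.0
        self.f_inh[t_idx] = 0.0
        if with_cooldown:
            self.cooldown[t_idx] = self.now + _SCAN_COOLDOWN_H
        if self._map_enter is not None:
            self._dirty_t[t_idx] = True
            self._dirty_m[partners[valid]] = True

    def _state_machine(self) -> None:
        now = self.now
        # Scans that completed: synapse or disengage.
        done_scan = np.flatnonzero((self.tmode == _SCANNING) & (self.phase_end <= now))
        for t in done_scan:
            m = self.tpartner[t]
            if m < 0 or not self.alive[m]:
                self._release(np.array([t]), with_cooldown=True)
                continue
            if self.rng_contact.random() < self.p.p_synapse:
                self.tmode[t] = _SYNAPSE
                self.phase_end[t] = now + self.p.synapse_duration_h
            else:
                self._release(np.array([t]), with_cooldown=True)
        # Synapses that expired.
        done_syn = np.flatnonzero((self.tmode == _SYNAPSE) & (self.phase_end <= now))
        self._release(done_syn, with_cooldown=True)

    def _candidate_pairs_naive(self, free_t: np.ndarray, free_m: np.ndarray):
        if len(free_t) == 0 or len(free_m) == 0:
            return {}
        tree = cKDTree(self.mpos[free_m])
        hits = tree.query_ball_point(self.tpos[free_t], self.contact_radius)
        out = {}
        for k, lst in enumerate(hits):
            if lst:
                out[int(free_t[k])] = [int(free_m[j]) for j in lst]
        return out

    def _rebuild_map(self, t_idx: np.ndarray, m_idx: np.ndarray) -> None:
        """Recompute contact windows for the given T rows / monocyte columns."""
        tv, mv = self._velocities()
        now = self.now
        r = self.contact_radius
        pairs = []
        if len(t_idx):
            pairs.append((np.repeat(t_idx, self.nm), np.tile(np.arange(self.nm), len(t_idx))))
        rest_t = np.setdiff1d(np.arange(self.nt), t_idx)
        if len(m_idx) and len(rest_t):
            pairs.append((np.repeat(rest_t, len(m_idx)), np.tile(m_idx, len(rest_t))))
        for ti, mi in pairs:
            dp = self.tpos[ti] - self.mpos[mi]
            dv = tv[ti] - mv[mi]
            c = np.einsum("ij,ij->i", dp, dp) - r * r
            a = np.einsum("ij,ij->i", dv, dv)
            b = 2.0 * np.einsum("ij,ij->i", dp, dv)
            enter = np.full(len(ti), np.inf)
            exit_ = np.full(len(ti), -np.inf)
            static = a < 1e-300
            touching = static & (c <= 0.0)
            enter[touching] = 0.0
            exit_[touching] = np.inf
            moving = ~static
            disc = b * b - 4.0 * a * c
            ok = moving & (disc >= 0.0)
            sq = np.sqrt(np.where(ok, disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_in = (-b - sq) / (2.0 * a)
                t_out = (-b + sq) / (2.0 * a)
            ok &= t_out >= 0.0
            enter[ok] = np.maximum(t_in[ok], 0.0)
            exit_[ok] = t_out[ok]
            self._map_enter[ti, mi] = now + enter
            self._map_exit[ti, mi] = now + exit_

    def _candidate_pairs_map(self, free_t: np.ndarray, free_m: np.ndarray):
        if self._map_enter is None:
            self._map_enter = np.full((self.nt, self.nm), np.inf)
            self._map_exit = np.full((self.nt, self.nm), -np.inf)
            self._dirty_t = np.ones(self.nt, dtype=bool)
            self._dirty_m = np.zeros(self.nm, dtype=bool)
        t_idx = np.flatnonzero(self._dirty_t)
        m_idx = np.flatnonzero(self._dirty_m)
        if len(t_idx) or len(m_idx):
            self._rebuild_map(t_idx, m_idx)
            self._dirty_t[:] = False
            self._dirty_m[:] = False
        now = self.now
        eps = 1e-9
        window = (self._map_enter <= now + eps) & (self._map_exit >= now - eps)
        out = {}
        if len(free_t) and len(free_m):
            sub = window[np.ix_(free_t, free_m)]
            r2 = self.contact_radius**2
            for k, t in enumerate(free_t):
                cols = free_m[sub[k]]
                if len(cols):
                    d2 = np.sum((self.mpos[cols] - self.tpos[t]) ** 2, axis=1)
                    verified = cols[d2 <= r2]
                    if len(verified):
                        out[int(t)] = [int(m) for m in verified]
        return out

    def _detect_contacts(self) -> None:
        now = self.now
        free_t = np.flatnonzero((self.tmode == _FREE) & (self.cooldown <= now))
        free_m = np.flatnonzero(self.alive & (self.engaged_by < 0))
        if self.config.contact_mode == "map":
            candidates = self._candidate_pairs_map(free_t, free_m)
        else:
            candidates = self._candidate_pairs_naive(free_t, free_m)
        for t in sorted(candidates):
            ms = [m for m in candidates[t] if self.engaged_by[m] < 0 and self.alive[m]]
            if not ms:
                continue
            d2 = np.sum((self.mpos[ms] - self.tpos[t]) ** 2, axis=1)
            m = ms[int(np.argmin(d2))]
            self.tmode[t] = _SCANNING
            self.tpartner[t] = m
            self.phase_end[t] = now + self.p.scan_duration_h
            self.engaged_by[m] = t
            if self._map_enter is not None:
                self._dirty_t[t] = True
                self._dirty_m[m] = True

    def _move(self) -> None:
        p = self.p
        dt = self.dt
        for pos, heading, moving, is_t in (
            (self.tpos, self.theading, self.tmode == _FREE, True),
            (self.mpos, self.mheading, (self.engaged_by < 0) & self.alive, False),
        ):
            pos[moving] += heading[moving] * (p.motion_speed * dt)
            lo = np.zeros(3)
            hi = np.array(self.env.box_size, dtype=float)
            if self.config.settled:
                hi = hi.copy()
                hi[2] = p.settle_height
            reflected = np.zeros(len(pos), dtype=bool)
            for d in range(3):
                below = pos[:, d] < lo[d]
                above = pos[:, d] > hi[d]
                pos[below, d] = 2 * lo[d] - pos[below, d]
                pos[above, d] = 2 * hi[d] - pos[above, d]
                heading[below | above, d] *= -1.0
                reflected |= below | above
            np.clip(pos, lo, hi, out=pos)
            if self._map_enter is not None and reflected.any():
                if is_t:
                    self._dirty_t[reflected] = True
                else:
                    self._dirty_m[reflected] = True

        # Re-orientation (run-and-tumble).  Draw counts depend only on the
        # motion stream, so they are identical across antibody doses.
        now = self.now
        for n, heading, next_tumble, is_t in (
            (self.nt, self.theading, self.t_next_tumble, True),
            (self.nm, self.mheading, self.m_next_tumble, False),
        ):
            due = next_tumble <= now
            k = int(due.sum())
            if k:
                heading[due] = self._unit_headings(k, self.rng_motion)
                next_tumble[due] = now + self.rng_motion.exponential(
                    1.0 / max(self.p.tumble_rate, 1e-9), k
                )
                if self._map_enter is not None:
                    if is_t:
                        self._dirty_t[due] = True
                    else:
                        self._dirty_m[due] = True

    # -------------------------------------------------------------- dynamics
    def _step_tcells(self) -> None:
        p = self.p
        dt = self.dt
        self.inhib += -p.k_general * (self.inhib - p.inhib_rest) * dt

        syn = self.tmode == _SYNAPSE
        self.f_cost[:] = 0.0
        self.f_inh[:] = 0.0
        if syn.any():
            partners = self.tpartner[syn]
            self.f_cost[syn] = hill(self.cd80_surf[partners], p.kd_cd28_cd80)
            free_pdl1 = self.pdl1_surf[partners] * self.unblocked
            self.f_inh[syn] = hill(self.pd1_surf[syn] * free_pdl1, p.kd_pd1_pdl1)

        _, self.act = compute_activation(self.f_inh, self.f_cost, self.f_acd3, self.inhib, p)

        quantum = p.pd1_prod_rate * self.act * dt
        self.pd1_int += quantum
        delays = self._sample_delays(self.rng_tr_t, self._tr_t_params, p.pd1_transloc_mean, self.nt)
        cols = (self.tick + self._delay_ticks(delays, self.Ht)) % self.Ht
        self.ring_t[np.arange(self.nt), cols] += quantum

        cur = self.tick % self.Ht
        due = self.ring_t[:, cur]
        moved = np.minimum(due, self.pd1_int)
        self.pd1_int -= moved
        self.pd1_surf += moved
        self.ring_t[:, cur] = 0.0

        # Activation-induced PD-1 turns over; the constitutive baseline is
        # homeostatically maintained.
        self.pd1_surf = self.pd1_base + (self.pd1_surf - self.pd1_base) * (
            1.0 - p.pd1_decay_rate * dt
        )

        emitted = p.ifng_secretion_rate * self.act * dt
        vox = self._voxel_indices(self.tpos)
        np.add.at(
            self.env.ifng_field.reshape(-1),
            np.ravel_multi_index(vox, self.env.ifng_field.shape),
            emitted / self.env.voxel_volume,
        )

    def _voxel_indices(self, pos: np.ndarray):
        shape = self.env.ifng_field.shape
        idx = []
        for d in range(3):
            idx.append(
                np.clip((pos[:, d] // self.env.voxel).astype(np.int64), 0, shape[d] - 1)
            )
        return tuple(idx)

    def _step_monocytes(self) -> None:
        p = self.p
        dt = self.dt
        vox = self._voxel_indices(self.mpos)
        local = self.env.ifng_field[vox]
        drive = hill(local, p.ifng_half_sat)
        drive = np.where(self.alive, drive, 0.0)

        delays = self._sample_delays(
            self.rng_tr_m, self._tr_m_params, p.mono_transloc_mean, (self.nm, 2)
        )
        rows = np.arange(self.nm)
        for j, (ring, rate, basal, horizon) in enumerate((
            (self.ring_pdl1, p.pdl1_prod_rate, p.pdl1_basal_rate, self.Hm),
            (self.ring_cd80, p.cd80_prod_rate, p.cd80_basal_rate, self.Hm),
        )):
            quantum = np.where(self.alive, (rate * drive + basal) * dt, 0.0)
            if j == 0:
                self.pdl1_int += quantum
            else:
                self.cd80_int += quantum
            cols = (self.tick + self._delay_ticks(delays[:, j], horizon)) % horizon
            ring[rows, cols] += quantum
            cur = self.tick % horizon
            due = ring[:, cur]
            if j == 0:
                moved = np.minimum(due, self.pdl1_int)
                self.pdl1_int -= moved
                self.pdl1_surf += moved
            else:
                moved = np.minimum(due, self.cd80_int)
                self.cd80_int -= moved
                self.cd80_surf += moved
            ring[:, cur] = 0.0

        # Death: constant hazard, independent of IFN-gamma.
        u = self.rng_death.random(self.nm)
        dying = self.alive & (u < -np.expm1(-p.mono_death_hazard * dt))
        if dying.any():
            self.alive[dying] = False
            orphans = self.engaged_by[dying]
            orphans = orphans[orphans >= 0]
            if len(orphans):
                self._release(orphans, with_cooldown=True)
            self.engaged_by[dying] = -1
            if self._map_enter is not None:
                self._dirty_m[dying] = True

    def _diffuse(self) -> None:
        p = self.p
        f = self.env.ifng_field
        for _ in range(self.n_sub):
            f = diffuse_ifng(f, self.sub_dt, p.diffusion_coeff, p.ifng_decay_rate, self.env.voxel)
        self.env.ifng_field = f

    # -------------------------------------------------------------- stepping
    def step(self) -> None:
        """Advance one slow tick."""
        self._state_machine()
        self._detect_contacts()
        self._step_tcells()
        self._step_monocytes()
        self._diffuse()
        self._move()
        self.tick += 1
        self.env.clock = self.now

    def agent_snapshot(self) -> pd.DataFrame:
        """Per-agent state table (one row per agent) at the current clock."""
        t = pd.DataFrame({
            "agent_id": [f"T{i}" for i in range(self.nt)],
            "type": "tcell",
            "subset": np.where(self.subset_cd4, "CD4", "CD8"),
            "pd1_surface": self.pd1_surf,
            "pdl1_surface": np.nan,
            "cd80_surface": np.nan,
            "act": self.act,
            "alive": True,
        })
        m = pd.DataFrame({
            "agent_id": [f"M{i}" for i in range(self.nm)],
            "type": "monocyte",
            "subset": "",
            "pd1_surface": np.nan,
            "pdl1_surface": self.pdl1_surf,
            "cd80_surface": self.cd80_surf,
            "act": np.nan,
            "alive": self.alive,
        })
        return pd.concat([t, m], ignore_index=True)

    def readout(self) -> ReadoutFrame:
        p = self.p
        for name, arr in (("pd1_surface", self.pd1_surf), ("ifng_field", self.env.ifng_field)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr.reshape(-1)))[0])
                raise SimulationDiverged(
                    f"non-finite {name} at t = {self.now} h (first offending index {bad})"
                )
        cd4 = self.subset_cd4
        pct4 = 100.0 * float(np.mean(self.pd1_surf[cd4] > p.pd1_pos_threshold)) if cd4.any() else 0.0
        pct8 = (
            100.0 * float(np.mean(self.pd1_surf[~cd4] > p.pd1_pos_threshold))
            if (~cd4).any() else 0.0
        )
        total = self.env.total_ifng()
        conc = total / (self.env.volume_um3 * 1e-12)  # a.u. per ml
        live = self.alive
        pctl1 = (
            100.0 * float(np.mean(self.pdl1_surf[live] > p.pdl1_pos_threshold))
            if live.any() else 0.0
        )
        return ReadoutFrame(
            time_h=self.now,
            pct_pd1_cd4=pct4,
            pct_pd1_cd8=pct8,
            ifng_total=total,
            ifng_conc_per_ml=conc,
            pct_pdl1_mono=pctl1,
            n_live_mono=int(live.sum()),
        )


def run_mlr(config: SimulationConfig, snapshot_dir=None) -> List[ReadoutFrame]:
    """Simulate one well to ``duration_h`` and return the requested readouts.

    A run is a pure function of (config, seed): identical inputs give
    bitwise-identical readout sequences.  Readout times are snapped to the
    nearest slow tick.  With ``snapshot_dir`` set, a per-agent state CSV is
    written at every readout time.
    """
    from pathlib import Path

    engine = _Engine(config)
    dt = engine.dt
    n_ticks = int(round(config.duration_h / dt))
    readout_ticks = sorted({int(round(t / dt)) for t in config.readout_times_h})
    frames: List[ReadoutFrame] = []
    pending = list(readout_ticks)

    def _emit() -> None:
        frames.append(engine.readout())
        if snapshot_dir is not None:
            outdir = Path(snapshot_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            engine.agent_snapshot().to_csv(
                outdir / f"agents_t{engine.now:07.1f}h.csv", index=False
            )

    if pending and pending[0] == 0:
        _emit()
        pending.pop(0)
    for _ in range(n_ticks):
        engine.step()
        if pending and engine.tick == pending[0]:
            _emit()
            pending.pop(0)
    return frames


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Per-replicate seed, shared across conditions of one titration.

    Conditions of the same replicate reuse the seed so dose effects are
    paired (common random numbers); replicates are independent.
    """
    return int(np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0] % (2**31))


def _final_frame_row(donor_id, condition, dose, replicate, frame: ReadoutFrame) -> dict:
    return {
        "donor_id": donor_id,
        "condition": condition,
        "dose_M": dose,
        "replicate": replicate,
        "time_h": frame.time_h,
        "pct_pd1_cd4": frame.pct_pd1_cd4,
        "pct_pd1_cd8": frame.pct_pd1_cd8,
        "ifng": frame.ifng_conc_per_ml,
        "pct_pdl1_mono": frame.pct_pdl1_mono,
    }


def run_dose_response(
    donor: DonorPhenotype,
    doses: Sequence[float],
    n_replicates: int,
    base_config: SimulationConfig,
    n_jobs: int = 1,
) -> DoseResponseTable:
    """Run the full titration protocol for one donor.

    One ``run_mlr`` per (condition, replicate), conditions being the
    no-antibody control, the anti-CD3-only control, and anti-CD3 plus each
    listed anti-PD-L1 dose.  The final readout of each run forms one table
    row.  Replicates use independent seeds; within a replicate, every
    condition shares the seed (paired design).
    """
    if len(doses) == 0:
        raise ValueError("doses must be non-empty")
    conditions: list[tuple[str, bool, float]] = [
        (COND_NO_ABS, False, 0.0),
        (COND_ACD3_ONLY, True, 0.0),
    ]
    for d in doses:
        if d < 0:
            raise ValueError("doses must be non-negative")
        label = COND_ACD3_ONLY if d == 0 else f"anti_pdl1_{d:.1e}"
        if d > 0:
            conditions.append((label, True, float(d)))

    jobs = []
    for rep in range(n_replicates):
        seed = replicate_seed(base_config.seed, rep)
        for label, acd3, dose in conditions:
            cfg = base_config.model_copy(
                update={
                    "donor": donor,
                    "anti_cd3_present": acd3,
                    "anti_pdl1_conc": dose,
                    "seed": seed,
                    "readout_times_h": [base_config.duration_h],
                }
            )
            jobs.append((label, dose, rep, cfg))

    def _one(job):
        label, dose, rep, cfg = job
        try:
            frames = run_mlr(cfg)
        except SimulationDiverged as exc:
            raise SimulationDiverged(
                f"condition {label}, replicate {rep}: {exc}"
            ) from exc
        return _final_frame_row(donor.donor_id, label, dose, rep, frames[-1])

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_one)(j) for j in jobs)
    else:
        rows = [_one(j) for j in jobs]
    df = pd.DataFrame(rows, columns=DoseResponseTable.COLUMNS)
    return DoseResponseTable(donor_id=donor.donor_id, df=df)
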