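# Methods

`mlrabm` is a hybrid agent-based / ODE simulator of the autologous
mixed-lymphocyte reaction (MLR) under anti-PD-L1 titration, plus the
statistics used to compare simulated and bench titrations.  This note
records the model, its assumptions, the calibrated defaults, the numerical
choices, and what the synthetic-data fixtures do and do not emulate.

## The well

The bench protocol plates 75×10³ memory T cells and 125×10³ monocytes in
200 µl over a flat-bottom 96-well (~0.32 cm²).  The simulated well is a
rectangular box holding `volume_scale` of that system (default 0.01 → 750
T cells + 1,250 monocytes).  The box *footprint* scales with
`volume_scale` and the depth follows from the scaled volume, so that when
cells settle their areal density equals the bench well's; at that density
the cell layer is near-confluent, which is what makes T-cell–monocyte
contact frequent enough for contact-borne signals to matter.  A
fully-suspended 3D mode (`settled: false`) exists, but at bench volumetric
density encounters in suspension are orders of magnitude too rare to
produce contact-driven dynamics in 4 days, so the settled mode is the
default.

The IFNγ field lives on a 50 µm voxel grid spanning the box.  The soluble
anti-PD-L1 antibody is a single well-mixed scalar: at 10⁻¹³–10⁻⁷ M it is
in vast molar excess over the receptors carried by ~2,000 cells, and
re-equilibration is fast relative to daily readouts, so neither depletion
nor antibody diffusion is modeled.

## T-cell state machine

Three occupancy signals, each a single-site (Hill-1) saturation — the
minimal form with saturating-binding semantics:

* `f_acd3 = acd3_dose / (acd3_dose + kd_cd3_acd3)` whenever anti-CD3 is
  present (the stimulus is a fixed saturating dose; `kd_cd3_acd3` is
  expressed relative to it);
* `f_cost = cd80 / (cd80 + kd_cd28_cd80)` against the synapse partner's
  surface CD80; zero without a live partner;
* `f_inh = x / (x + kd_pd1_pdl1)` with `x = pd1_surface × pdl1_free`, the
  mass-action encounter product of the T cell's own surface PD-1 and the
  partner's *unblocked* PD-L1.  Blockade is equilibrium competitive
  occupancy: `pdl1_free = pdl1_surface · kd_ab / (kd_ab + [Ab])`.

These combine into the drive
`acoeff = −k_inh·f_inh + (1 + k_cost·f_cost)·(k_acd3·f_acd3)` and the
hidden activation
`act = clamp₀₁((1 + tanh(β(acoeff − θ)))/2 + inhib_general)`.
Activation is deliberately a hidden variable: surface PD-1 is reported in
percent-positive terms, not receptor counts, so the map from internal
drive to measurable marker goes through this bounded function.

`inhib_general` aggregates the slow, unmeasured inhibitory mechanisms that
wind the response down late in the assay (exhaustion-like programs,
regulatory feedback).  It relaxes toward a configurable resting value at
rate `k_general`; the default resting value is negative (−0.6), so the
pool drains activation with a ~40 h time constant.  This choice — a
bounded relaxation law with an explicit resting parameter rather than an
unbounded drift — is deliberate: it is the simplest form that yields the
observed rise-then-fade kinetics without diverging.

PD-1 handling separates a constitutive baseline from an activation-induced
pool.  The baseline is drawn per agent at initialization (below) and
treated as homeostatically maintained.  Production adds
`pd1_prod_rate · act · dt` to an internal pool; each produced quantum
surfaces after a stochastic log-normal delay (`pd1_transloc_mean` = 24 h,
CV 0.5 — receptor upregulation appears on the membrane on the day
timescale, which is what delays the %PD-1⁺ peak to ~72 h); induced surface
PD-1 turns over at `pd1_decay_rate`.  IFNγ is emitted as
`ifng_secretion_rate · act · dt` into the agent's voxel.

## Monocyte state machine

Monocytes have no hidden activation.  Their normalized cytokine response
is `drive = c/(c + ifng_half_sat)` with `c` the IFNγ concentration of
their voxel.  PD-L1 and CD80 are produced at `rate·drive + basal` and
surface through the same produce-then-translocate scheme (shorter delay,
0.5 h).  CD80 and CD86 are not distinguished; one co-stimulatory pool
faces CD28.  Monocyte death is a constant hazard (`mono_death_hazard`,
0.02 h⁻¹ → ~15 % alive at 96 h), explicitly independent of IFNγ — direct
cytokine toxicity is excluded by design, the decline is the assay's
intrinsic monocyte attrition.

## Motion, contacts, synapses

Cells crawl at `motion_speed` (360 µm/h ≈ 6 µm/min) in an unbiased
run-and-tumble walk (re-orientation rate 2 h⁻¹), reflecting at walls; in
settled mode motion is lateral within a thin bottom layer.  When a free
T cell comes within contact radius (`tcell_radius + mono_radius` = 12 µm)
of a free live monocyte it scans for `scan_duration_h` (0.1 h), then forms
a synapse with probability `p_synapse` (0.5) or disengages (with a short
cool-down so a failed scan does not retry every tick).  Synapsed pairs
freeze, exchange `f_cost`/`f_inh` every tick for `synapse_duration_h`
(1 h), then separate.  Contact signals exist only inside a synapse.

Contact detection has two interchangeable implementations: a per-tick
spatial query (k-d tree; the default) and an interaction-map scheduler
that predicts closed-form first-contact windows per motion segment
(headings are piecewise constant, so pair distance is a quadratic in
time) and only verifies candidates whose window covers the current tick.
The two are bitwise equivalent — the map is a candidate filter with no
false negatives — which the test suite asserts on 50-agent scenes.  The
per-tick query is the default because at 2,000 agents its O(n log n) per
tick beats maintaining O(n²) pair windows.

## Donor-specific initialization

Flow cytometry summarizes a marker as a geometric mean intensity and a
percent of cells above a positivity gate.  Two statistics pin down the two
parameters of a log-normal: per-agent baseline levels are sampled with
geometric mean `geo_mean` and dispersion
`σ = ln(gate/geo_mean) / z₁₋p` (standard-normal quantile `z`), clamped to
[0.05, 3].  Gate-on-the-median leaves σ unconstrained (default 0.8);
impossible combinations (e.g. a minority tail on the wrong side of the
geometric mean) raise a dedicated error rather than silently clamping.
The same gate (`pd1_pos_threshold`) is used at readout, so an unstimulated
well reports the donor's baseline percent-positive by construction.
CD4 and CD8 agents share one dynamics model; the subset label only
stratifies initialization and readout.

## Calibration

Free rate constants were calibrated once, jointly, against four
qualitative kinetic milestones of the stimulated assay — %PD-1⁺ peaking at
the 72 h readout, monocyte %PD-L1⁺ ≥ 80 % by 24 h, total IFNγ peaking at
72–96 h, and an unstimulated well staying within ~2 points of baseline
%PD-1⁺ — plus an emergent dose response with EC50 inside the tested grid.
The antibody affinity default `kd_ab = 10⁻¹¹ M` sits in the
experimentally observed per-donor EC50 range.  Diffusion
(`1.1×10⁴ µm²/h`) and decay (`0.008 h⁻¹`) of IFNγ are *calibrated
effective* values for a crowded settled culture, not measured constants;
they control how sharply the cytokine pools near the cell layer and how
late total IFNγ peaks.  Calibration was performed at the default scale
(2,000 agents, 96 h, 3 seeds per condition) and the resulting defaults are
frozen in `ModelParameters`; `mlr-abm calibrate` re-checks the milestones
for any parameter file.

## Randomness and reproducibility

Each run derives five independent PCG64 streams (motion, contact
outcomes, monocyte death, T-cell and monocyte translocation delays) from
its seed.  Streams whose draw counts cannot depend on treatment (motion,
death, translocation — draws are made for every agent every tick) consume
identically across antibody doses; within one replicate of a titration,
every condition reuses the replicate's seed.  Dose contrasts are therefore
paired comparisons (common random numbers): the baseline sampling noise
that dominates seed-to-seed %-positive variation cancels across doses,
which is why mean dose-response curves are cleanly monotone at modest
seed counts.  Replicates use independent seeds.  A run is a pure function
of (config, seed); the full synth → simulate → analyze pipeline is
byte-reproducible.

## Numerics

* Agent ODEs: explicit Euler at `dt_slow` (0.1 h), matching the rule-based
  tick structure; a stability guard rejects steps that under-resolve the
  fastest decay rate.
* Diffusion: explicit 7-point stencil sub-stepped at `dt_fast` ≤ h²/(6D),
  asserted at startup and on every call; zero-flux boundaries by edge
  padding; decay applied as an exact exponential factor.  Mass is
  conserved by diffusion to floating-point accuracy.
* Translocation queues are bucketed at tick resolution in the vectorized
  engine (ring buffer); the per-agent API keeps explicit (amount, due)
  queues.  Delays are capped at mean·(1 + 6·CV).
* Readout times snap to the nearest slow tick.
* Time-step sensitivity: halving both steps shifts 48–96 h readouts by a
  few percent (the scan/synapse cycle is quantized at `dt_slow`), not the
  sub-percent level of the smooth ODE parts; the suite asserts an 8 %
  band.  `dt_slow = 0.1 h` is the accuracy/runtime point chosen for the
  defaults.
* Sigmoid fits run `scipy.optimize.curve_fit` in log-dose with Hill slope
  fixed at 1 (three parameters: Bottom, Top, log EC50), multi-started over
  a 7-point log-EC50 grid spanning one decade beyond the dose range, with
  tight tolerances; a span statistically indistinguishable from zero flags
  the EC50 unidentifiable, and zero-dose controls map to a pseudo-dose one
  decade below the lowest tested dose.
* RANSAC is the classical sample-consensus loop (minimal sets of 2, 500
  trials, consensus by absolute residual, OLS refit on the consensus); the
  default residual threshold is 2.5×1.4826×MAD of OLS residuals with an
  absolute floor for exactly-collinear input.  `threshold=inf` reduces it
  to OLS exactly.

## Synthetic data

`synthetic_data` generates donor cohorts (log-normal phenotype
heterogeneity across donors) with hidden per-donor true sigmoids, and
noisy triplicate titration tables (Gaussian, homoscedastic in span units,
truncated to [0, 100]; optional heavy-tailed contamination for robustness
tests).  It emulates the *statistical shape* of bench titrations — means,
triplicate scatter, donor spread — not their biology: passing recovery
tests shows the fitting and screening machinery is correct and the
simulator is internally consistent, not that the model predicts any
particular donor's bench response.  Real-data features deliberately not
imitated: heteroscedastic plate effects, inter-day drift, flow-gating
artifacts, and raw cytometry event data.

## Known limitations

* No TCR specificity, MHC presentation, Tregs, B cells, CTLA-4/TGF-β or
  cytokines beyond IFNγ; one co-stimulatory pool stands in for CD80/86.
* No crowding or adhesion mechanics beyond the contact radius; cells can
  overlap.
* Receptor units are arbitrary fluorescence-scale units; IFNγ is in
  arbitrary amount units (reported both as total and per-ml equivalent so
  values are comparable across `volume_scale`).
* The monocyte %PD-L1⁺ readout saturates at 100 % in stimulated wells —
  above the ~90 % plateau seen on the bench.
* Calibration targets qualitative kinetics; absolute accuracy against any
  real donor requires fitting the donor's own titration.
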