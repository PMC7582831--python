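# Methods

## The model

`cyclosim` describes a neonatal ventricular myocyte as three well-mixed
compartments — bulk cytosol (CYT, volume fraction 0.70), a thin plasmalemmal
shell (PM, 0.05) and an outer-mitochondrial-membrane shell (OMM, 0.05) —
each holding one cyclic nucleotide (cAMP or cGMP, modelled independently).
For compartment *i* with concentration S<sub>i</sub> (μM):

    dS_i/dt = Σ_c J_c  −  Σ_p a_p (1 − φ_p) Vmax_p S_i / (Km_p + S_i)  +  Σ_j k_ij (S_j − S_i)

* **Synthesis** is zero-order per cyclase source, scaled by treatment.
  Adenylyl cyclases (AC) run at `J_basal · stim`, with `stim` between 1 and
  `max_stim_factor` (default ceiling 4); isoprenaline engages half the
  stimulation reserve, forskolin 0.9 of it (its dose–response is not part of
  the kinetic scheme; 0.9 keeps strongly stimulated states clearly below the
  reporter ceiling so the terminal saturation control stays visible).
  Soluble guanylyl cyclase (sGC) is split into a reduced branch, activated
  by NO-type drives (endogenous `no_input`, SNAP, Bay 41-2272), and an
  oxidised fraction that ignores NO but responds to cinaciguat; both
  branches saturate at a 6-fold ceiling.
* **Hydrolysis** is Michaelis–Menten per PDE family. Km and specific-Vmax
  values for PDE8 (0.06 μM, 0.15 μmol·min⁻¹·mg⁻¹), PDE4 (5 μM, 0.03) and
  PDE2A (10 μM for cGMP, 30 μM for cAMP) are the tabulated constants for
  these enzymes; the remaining Km/Vmax entries in `PDE_KINETICS` are
  literature-typical defaults. A per-compartment density factor converts the
  specific activity into a local `vmax` in μM·s⁻¹; it absorbs the unknown
  enzyme amount per compartment and is the quantity the genotype tables and
  the inference stage rescale.
* **Exchange** is first-order and volume-corrected so total mass is
  conserved; each coupling is declared on exactly one side of a pair.
  Default topology: PM↔CYT and OMM↔CYT, no direct PM↔OMM path.

Steady states are found by damped root-finding on the RHS in
log-concentration space (positivity by construction) with a long-horizon
integration fallback; a capacity pre-check raises a `NoSteadyStateError`
when synthesis can outrun total Vmax. Time courses use LSODA with
rtol 1e−8 / atol 1e−10 μM, restarting at each drug-addition event; drugs act
as instantaneous steps (frames arrive every 10 s, so sub-frame binding
kinetics are not identifiable).

## Pharmacology

Family-selective inhibitors at their experimental working doses are
modelled as complete block of the primary family (occupancy 1), because the
assay interprets each inhibitor's ΔR/R0 as that family's full activity;
documented off-target action is kept (sildenafil occupies PDE1 at
10/(10+0.1) ≈ 0.99 via its 0.1 μM IC50). IBMX blocks every family.
Occupancies compose by maximum per target (idempotent, order-independent,
and IBMX dominates any selective inhibitor); cyclase drives compose per
drug, so distinct stimuli add while re-application is a no-op.

## The control and dystrophic cells

The control cAMP model splits AC output between a bulk-accessible pool
(read by the cytosolic reporter) and a PM-local pool feeding the weakly
coupled shell. PDE4 carries most regulated cytosolic hydrolysis, PDE2A is a
large low-affinity reservoir, and the OMM is a passive shell whose
high-affinity PDE8 complement pins its standing cAMP below the bulk level.
The cGMP model places sGC in all three compartments; the OMM pool has its
own NO supply.

The dystrophic (mdx) cell is the control model transformed by a genotype
factor table (`MDX_CAMP_FACTORS`, `MDX_CGMP_FACTORS`). The factors are
**calibration defaults, not measurements**: they were chosen (by a
constrained numerical search over deterministic ordering margins and
mini-cohort t-statistics) so that the virtual cohorts reproduce the full
set of qualitative control-vs-mdx differences the package targets — lower
basal cGMP in cytosol and PM but not at the OMM, the oxidised PM sGC pool
revealed by cinaciguat, higher bulk basal cAMP with less PDE4, blunted
isoprenaline/forskolin responses, unchanged PM cAMP behaviour, and lower
OMM cAMP despite the higher bulk level. Key entries:

* cGMP: endogenous NO drive ×0.4 in CYT and PM (the mitochondria-proximal
  source is spared); total sGC ×1.3 with the *excess* oxidised (cytosolic
  oxidised fraction 1 − 1/1.3, PM fraction 0.5 vs 0.1) so the functional
  reduced-branch pool is unchanged — this is what lets saturating
  SNAP + Bay 41 equalise cytosolic cGMP; per-family PM PDE increases
  (PDE5 ×2.25, PDE2A ×1.65, PDE1 ×1.8). A uniform PM-PDE factor cannot
  produce larger inhibitor deltas in mdx: in the near-linear regime it
  cancels out of every relative response.
* cAMP: CYT PDE4 ×0.43 and PDE8 ×0.5, PDE3 ×1.5; OMM PDE8 ×3; PM complement
  nearly neutral (PDE4 ×1.05, PDE8 ×0.85); stimulation reserve of the
  *bulk* AC pool ×0.6 while the PM-local pool couples normally. The spared
  PM pool plus the shell's weak exchange is the compartmental rendering of
  the sub-membrane-trapping hypothesis: the PM makes and keeps its normal
  stimulated cAMP while the bulk sees less, both from its own weakened AC
  pool and from the small shell efflux. An optional exchange factor in
  `GenotypeFactors` can additionally slow PM→CYT transfer; the calibrated
  defaults do not require it.

The mitochondrial paradox needs no extra ingredient: tripled OMM PDE8 holds
mdx basal OMM cAMP far below control (high-affinity, so it clamps hardest
at low concentrations), and on stimulation PDE8 saturates, letting the mdx
OMM signal rise proportionally more even though its absolute level stays
lower. On the factor grid {0.5, 1, 2, 3, 4}, the conjunction (bulk cAMP
higher AND OMM cAMP lower in mdx) first appears at factor 2 — only
redistribution toward the OMM reproduces both basal observations at once.

## Sensors

Each reporter variant is a Hill transfer function
R(c) = r_min + (r_max − r_min)·cⁿ/(cⁿ + EC50ⁿ) from local concentration to
the background-subtracted 480/545 nm emission ratio. Defaults: cGMP family
EC50 0.5 μM, cAMP family 4 μM, n = 1, r_min 1.0, r_max 1.5 (cytosolic) or
1.3 (targeted variants, reflecting the usual dynamic-range compression of
targeted fusions). These are literature-typical placeholders exposed in the
registry — the measured values for these constructs are not available.
Sensor buffering of the analyte is neglected. The inverse transform and a
plateau-based zero/saturating calibration are provided.

## Trace pipeline

R_t = (donor − background)/(acceptor − background); R0 is the mean of the 8
frames preceding the stimulus (0-based indexing, event frame = first frame
after the addition); responses are plateau means of R/R0 minus the
pre-event reference (1.0 for the stimulus, the previous plateau for chained
additions). A plateau is the *latest* window of 6 frames whose fitted slope
magnitude is below max(1e−3 per frame, 2·SE(slope)); the SE term keeps the
rule usable on noisy traces while a noiseless ramp is still rejected.
Optional linear detrending divides out a baseline-fitted line,
scale-preservingly. The saturation headroom is the further rise caused by
the terminal IBMX(+forskolin) addition; headroom > 0 is the per-cell
non-saturation control.

## Synthetic cohorts

A virtual cell multiplies every PDE activity, cyclase rate and exchange
constant by independent mean-one lognormal noise (σ = 0.2 on the log scale;
a placeholder for biological replicate scatter, deliberately generous).
Traces are synthesised by splitting the sensor ratio into
constant-sum donor/acceptor channels, applying per-channel exponential
bleaching (ratio-neutral equal rates by default; a differential mode
exercises detrending), 1% Gaussian read noise and a background offset.
Randomness is counter-based — every cell's generator derives from
(seed, scenario name, genotype, cell index) — so cohorts are bitwise
reproducible and independent of generation order and cohort composition.
The default cohort covers 32 scenarios (basal inhibitor panels, stimulus
responses and the PM cinaciguat experiment, in all three compartments for
both nucleotides) with 8 cells per genotype per scenario; chained
stimulus-then-inhibitor protocols are in the library as well. These sizes
keep a full cohort generation-plus-analysis run around a minute while every
targeted comparison is decisively powered.

What the generator does *not* emulate: imaging optics and segmentation,
spectral bleed-through beyond a scalar background, receptor desensitisation
or washout, sensor photophysics, and culture-level nesting of cells.
Passing tests therefore demonstrate internal consistency of model,
pipeline and statistics under realistic noise — not instrument-level
realism.

## Statistics and the ordering report

Two-group comparisons use Welch's t (a pooled-variance option exists);
multi-group comparisons use one-way ANOVA with Bonferroni-corrected pairs
(p_adj = min(1, m·p)); stars follow the ``*`` 0.01 ≤ p ≤ 0.05, ``**``
0.001 ≤ p < 0.01, ``***`` p < 0.001 convention. The genotype ordering
report tests each expected difference at α = 0.05. *Absence* of a
difference is accepted when the test is non-significant **or** the observed
difference is below 10% of the response scale: a pure p ≥ α rule would fail
its own 5% type-I rate per equality check even when the generator makes the
groups identical, so the equivalence margin (set far below every
directional effect in the calibrated model) is what makes "no difference"
a stable property rather than a coin flip.

## Enzyme-activity inference

`estimate_pde_activity` inverts the steady-state model: activity scalars
(log-parameterised, so positive) are fitted by least squares so that
predicted inhibitor ΔR/R0 values match the observed panel. Panels are
summarised by 20%-trimmed means — under lognormal cell heterogeneity the
plain mean delta is biased a few percent away from the homogeneous-template
prediction, and the trimmed mean tracks the typical cell that the template
actually describes. Confidence intervals are deliberately conservative:
the hull of the bootstrap (B = 1000, cell-resampling, seeded) percentile
and normal intervals, widened by the spread between mean- and
median-aggregated fits as a data-driven allowance for aggregation
sensitivity. In the validation study (benchmark single-compartment
template, four families at comparable capacity, 50 cells/group, σ = 0.2,
1% channel noise, 20 replicates) this reaches ≤ 15% worst-case recovery
error with ~95% CI coverage, where the plain mean/percentile construction
undercovers. Cells whose parameter draw has no finite steady state under an
inhibitor would saturate the reporter; they are excluded, as the
experimental non-saturation control excludes them. Panels with fewer
independent treatments than unknowns raise an identifiability error naming
the unconstrained parameters.

## Numerical choices and degenerate inputs

* Integration: LSODA, rtol 1e−8, atol 1e−10 μM; event-time restarts.
* Steady state: hybrid root-finding in log space, residual tolerance scaled
  to the synthesis rate; models with zero synthesis return zeros.
* Single-compartment inversions use Brent's method on the scalar balance.
* Degenerate statistics (identical constant groups) return p = 1 rather
  than NaN.
* Protocol windows: additions at 300 s, terminal saturation at 800 s
  (cGMP) or 1000 s (cAMP — the near-saturated PDE8 dynamics settle more
  slowly), 500–700 s of saturating segment; all exposed per protocol.

## Known limitations

* The mdx genotype tables are calibrated to reproduce orderings, not fitted
  to data; their absolute magnitudes should not be read as measurements.
* PDE2A's cGMP-stimulated cAMP hydrolysis (allosteric cross-talk) is not
  modelled; neither are Ca²⁺, PKA/PKG feedback, or receptor kinetics beyond
  a stimulation factor.
* Under complete PDE2A block the dystrophic cytosol has no finite steady
  state (its remaining PDE4 capacity is below basal synthesis); simulated
  traces then rise until the sensor compresses them. This is a real
  property of the calibrated model, handled by the saturation controls.
* Compartment volumes, exchange constants and sensor parameters are design
  defaults; all are exposed through the configuration layer.
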