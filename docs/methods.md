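# Methods

## Transport model

The kinetic core treats each cell as two well-mixed compartments. State
variables are the phosphorylated sensor fraction `p ∈ [0,1]` and the nuclear
and cytoplasmic concentrations `N`, `C` (arbitrary concentration units).
Fluxes across the nuclear envelope are first order:

* **Active import** `k_in(p) = k_in_max · σ((S_eff − s_half)/s_width)` with
  `S_eff = nls_score − delta_score_phospho · p` and `σ` the logistic
  function. The literature characterises bNLS strength with a dimensionless
  prediction score and reports the qualitative consequences (stronger score →
  more nuclear; phosphorylation weakens import) but no rate law; the logistic
  is our choice — the simplest smooth, saturating, monotone map. It is
  deliberately steep (`s_width` default 0.6 score units) because sensors one
  to two score units apart behave very differently in cells.
* **Active export** `k_out`, constant per condition; leptomycin B is modelled
  as `k_out → 0` (`leptomycin()`), nothing else.
* **Passive pore diffusion** `k_d = k_diff0 · σ((mw_half − mw·copies)/mw_width)`,
  a declining function of the *effective* mass (monomer mass × oligomer copy
  number). Defaults (`mw_half` 60 kDa, `mw_width` 8 kDa, `k_diff0` 1/min)
  place ~34 kDa fusions in the fast-equilibration regime and ~64 kDa fusions
  in the strongly hindered regime.

With synthesis `σ_s` (cytoplasm only), uniform degradation `δ` and nuclear/
cytoplasmic volume ratio `r` (default 0.5), the concentration equations carry
`r` factors so compartment *amounts* balance; a closed system conserves total
sensor exactly (RK4 preserves linear invariants, so conservation holds to
floating-point roundoff, far inside the 1e-9 tolerance asserted in tests).

Setting `dN/dt = 0` gives the closed-form steady-state ratio
`C/N = (k_out + k_d + δ)/(k_in(p*) + k_d)` with
`p* = k_phos·a/(k_phos·a + k_dephos)`. This is the long-time limit of the
integrator whenever a steady state exists (turnover present, or closed
system). A useful exact property used by the validation tests: the total
amount obeys the autonomous equation `total' = σ_s − δ·total`, so a
trajectory initialised at any steady state keeps its total fixed and
converges to the new ratio at the *fast* exchange eigenvalue
`k_out + k_d + r(k_in + k_d) + δ` (the 2×2 exchange matrix has eigenvalues
exactly `−δ` and minus that sum).

**Integrator.** Fixed-step classical RK4, default step 0.05–0.1 min,
sub-stepping when the activity grid is coarser; a stability guard rejects
steps with `dt · max_rate > 2`. Deterministic by construction.

**Default rate constants** (`TransportParams`): `k_in_max` 1/min, `s_half`
10, `s_width` 0.6, `delta_score_phospho` 4, `k_out` 0.005/min, `k_diff0`
1/min, `mw_half` 60 kDa, `mw_width` 8 kDa, synthesis 0.01 conc/min,
degradation 0.01/min, `k_phos` 1/min, `k_dephos` 0.1/min. These were chosen
once to embody the documented sensor phenomenology: resting C/N strictly
decreasing across bNLS scores {8, 10.5, 11.5, 12.5, 15.5}; agonist fold
change > 1.5 only for the three mid scores (the weakest sensor barely
imports; the strongest keeps > 0.8·k_in_max even fully phosphorylated); and a
larger agonist-induced shift for a 64 kDa than for a 34 kDa fusion.

**Known limitation (export block).** Because `k_out` is shared across
sensors, the *relative* C/N change when export is blocked,
`k_out/(k_out + k_d + δ)`, is the same for every bNLS score. Real sensor
series show large drops for mid-score sensors and essentially none for
weak-import sensors. The defaults keep `k_out` small so the weak-import
sensor moves < 5 % (as observed) and mid-score sensors still strictly
decrease; the magnitude of their drop is not reproduced. Capturing it would
require sensor-specific effective export (e.g. import/export site
competition), which we deliberately left out: phosphorylation acts on import
only, and export strength is constant.

## Pharmacology and activities

Each agent has a target pathway (PKA, ERK, calcium, export), a mode
(agonist, kinase inhibitor, export blocker), a Hill dose-response
(`ec50`, `hill`) and time constants `tau_on`/`tau_off`. A schedule event sets
a zero-order-held target (no washout unless overridden); observed activity
relaxes to the target, `da/dt = (a_target − a)/τ`, using the latest acting
agent's `tau_on` when rising and `tau_off` when falling (inhibitor `tau_off`
3 min). Targets add linear crosstalk `c_{j→i}(a_j − baseline_j)` and are
clipped to [0,1]. Default crosstalk encodes the strongly asymmetric PKA/ERK
coupling: PKA→ERK −0.5, ERK→PKA +0.15; baselines 0.05 (PKA) and 0.20 (ERK).
Default dose-responses: Fsk EC50 3 µM (hill 1), EGF EC50 0.3 nM, H89 1 µM,
VX11e 100 nM, PMA 50 nM. Calcium: ATP produces a transient
(rise τ 0.3 min, decay τ 1.8 min — back within 5 % of baseline ~8 min after
addition); A23187 a sustained plateau; an optional PKA-dependent gain
(default 1.5×) scales the indicator when a PKA trace is supplied.

No receptor/cAMP mechanism, no spatial transport, no stochastic
single-molecule kinetics — the activity layer is a phenomenological driver
for the transport model.

## Synthetic microscopy

`sample_field` rejection-samples non-overlapping elliptical cells (semi-axes
24–34 px at the default 0.5 µm/px) with elliptical nuclei strictly inside
(40–52 % of the cell axes), kept ≥ 12 px from the border so moderate drift
cannot truncate them. `render_stack` composes per-frame expected images —
ER marker as a bright nuclear rim plus thresholded band-limited "tubule"
texture (cosmetic, non-contractual), KTR channels filled with the true
compartment concentrations, optional whole-cell calcium channel — then
applies `expected = gain·conc + background`, Poisson shot noise, Gaussian
read noise, integer-pixel drift with constant-background padding, and uint16
clipping (saturation above 1 % of pixels is logged). Optional
`fixation_scale` multiplies (cytoplasmic, nuclear) concentrations
asymmetrically to emulate the C/N distortion introduced by fixation; the
ground truth is unaffected, which is exactly the point — analyses of fixed
and live material should not be compared.

Cell-to-cell heterogeneity in `run_experiment`: lognormal expression scale
(σ = 0.25; moves intensities, not C/N) and a mild per-cell activity
amplitude jitter (σ = 0.08, clipped to [0.5, 1.5]). What the generator does
*not* emulate: optics (no PSF), 3-D structure, cell migration, division,
segmentation-hostile morphologies (touching cells appear only by disabling
the placement halo), autofluorescence gradients and uneven illumination.
Passing recovery tests therefore demonstrate correctness of the measurement
logic, not robustness to every real-world artefact.

All randomness flows from the single experiment seed through named
`SeedSequence` substreams (geometry, jitter, render, drift per field), so a
seed fully determines every output byte.

## Segmentation and ROI sampling

Default marker morphology is the ER/nuclear-envelope pattern, chosen so both
compartments come from one channel. Foreground is Otsu on log-intensities
(flat images yield no labels rather than an error). In `er_rim` mode nuclei
are the enclosed holes of the thresholded support, grown back by one pixel
(the rim overlaps the outermost pixel of the true nucleus); `nuclear_fill`
handles H2B-like markers. Objects under 200 px are removed; touching nuclei
are split by distance-transform watershed. Cytoplasm is nearest-nucleus
expansion (up to 40 px) within the filled marker support, minus a 2-px guard
ring that excludes the envelope rim from cytoplasmic measurements;
border-touching cells are dropped, as are cells whose guard ring consumes
the whole cytoplasm (all drops logged). ROI-disk pairs (default radius 5 px)
are placed uniformly among all centres whose distance transform exceeds the
radius — a seeded, automated version of manually drawn ROI pairs; whole-
compartment masks are the default measurement support because they are
strictly more precise, with disks available as a fidelity mode.

## Measurement

Stacks are registered to frame 0 by integer-pixel phase cross-correlation on
the marker channel, the same shift applied to all channels. Background
defaults to the per-frame mode of non-cell pixels — the underlying
acquisition convention is rarely stated in imaging work, so `median`,
`none` (raw means) and fixed values are provided and the choice is recorded
in the output. A measurement is flagged invalid when either background-
subtracted mean is nonpositive. Per-cell traces carry a first/last-frame
validity check: the marker signal over the cell's region at the last frame
must retain ≥ 50 % of its first-frame (background-subtracted) level,
otherwise the cell left its ROI and the trace is excluded from aggregation
by default. `cn_ratio` and `c_over_total = C/(C+N)` are exported side by
side; they are exact bijections of one another.

## Statistics

The statistical unit is the image: valid cells are averaged per image
(warning below 10 cells), and image means enter mean ± SEM, tests and dose
tables. The t-test is two-tailed Welch by default (pooled-variance flag
available) with the convention p = 1 for two zero-variance equal-mean
groups. Two-way ANOVA is fixed-effects with interaction, type II sums of
squares for unbalanced designs (via statsmodels); a single-level factor
degrades to one-way with a warning, and the interaction is dropped without
within-cell replication. Raw p values are reported; Benjamini–Hochberg is
available but off, matching common practice of reporting unadjusted values.
Response metrics summarise replicate time courses as fold change vs the
pre-event baseline window; `t_signif` is the first post-event time a paired
t-test across ≥ 3 replicates gives p < α, `t_half` the first crossing of
halfway between 1 and the plateau fold (plateau = mean of the last 5
samples; traces with plateau fold within 5 % of 1 are reported as flat).
Dose-response tables are dose-sorted with a monotonicity flag from the
better of an increasing/decreasing isotonic fit (normalised residual RMS
< 5 %).

## Problem sizes in the validation suite

The acceptance-style checks run on synthetic experiments of 4 fields ×
14 cells × 60 one-minute frames at 352×352 px (≥ 50 recovered cells), chosen
as the smallest design that exercises every pipeline stage with comfortable
statistics; the null-calibration study uses 2000 simulated two-group
experiments at the image-mean level (2 × 3 images × 12 cells). The
closed-form/ODE cross-check integrates each random parameter set for 25
e-folds of its analytically known slowest excited mode.
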