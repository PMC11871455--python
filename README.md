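# ktrkit

Simulation and quantification of **kinase translocation reporter (KTR)**
imaging experiments.

KTRs are fluorescent fusion proteins that shuttle between the nucleus and the
cytoplasm of living cells. The sensor domain carries a bipartite nuclear
localization signal (bNLS) that the cognate kinase phosphorylates, weakening
import, plus a constitutive nuclear export signal (NES); passive diffusion
through nuclear pores adds a size-dependent leak. The per-cell
cytoplasm-to-nucleus fluorescence ratio

```
C/N = (mean cytoplasmic counts − background) / (mean nuclear counts − background)
```

therefore reads out kinase activity: more activity → weaker import → higher
C/N. ktrkit is for cell biologists and imaging analysts who build or use such
reporters (PKA, ERK) and want (a) a mechanistic sandbox for sensor design —
how bNLS strength scores, fusion size and oligomeric state set the resting
distribution and dynamic range — and (b) a fully testable measurement
pipeline, validated end to end against a synthetic-microscopy generator with
exact ground truth.

## The model

Each cell is a two-compartment exchange system in nuclear and cytoplasmic
concentrations *N*, *C* with phosphorylated sensor fraction *p*:

```
dp/dt = k_phos·a·(1−p) − k_dephos·p                     (a = kinase activity ∈ [0,1])
dN/dt = (k_in + k_d)·C − (k_out + k_d)·N − δ·N
dC/dt = σ + r·(k_out + k_d)·N − r·(k_in + k_d)·C − δ·C   (r = V_nuc/V_cyto)
```

with logistic rate maps
`k_in = k_in_max · logistic((S_eff − s_half)/s_width)`, where the effective
bNLS score `S_eff = score − Δscore·p` drops with phosphorylation, and
`k_d = k_diff0 · logistic((mw_half − mw·copies)/mw_width)` for the passive
leak. The steady-state ratio has the closed form

```
C/N = (k_out + k_d + δ) / (k_in(p*) + k_d),   p* = k_phos·a / (k_phos·a + k_dephos)
```

Treatment schedules (forskolin, H89, EGF, VX11e, PMA, leptomycin B, ATP,
A23187) drive kinase activities through Hill dose-response and first-order
relaxation, with asymmetric PKA↔ERK crosstalk (PKA suppresses ERK; ERK weakly
induces PKA). The imaging layer renders fields of elliptical cells — an
ER/nuclear-envelope marker channel, KTR channels, optional calcium channel —
with Poisson shot noise, Gaussian read noise and rigid stage drift, paired
with exact per-cell ground truth. The measurement layer registers, segments
nucleus and cytoplasm from the marker channel alone, samples optional random
ROI-disk pairs, extracts per-cell C/N traces, and aggregates them with the
image (not the cell) as the statistical unit for SEM, Welch t-tests and
two-way ANOVA.

## Worked example

`examples/01_sensor_tuning.py` scans a bNLS-score series of PKA sensors:

```
 score  C/N rest  C/N stim   fold  C/N +LMB
   8.0     0.953     1.040   1.09     0.941
  10.5     0.365     1.025   2.81     0.361
  11.5     0.302     0.969   3.21     0.298
  12.5     0.288     0.772   2.68     0.284
  15.5     0.285     0.294   1.03     0.281
```

Resting C/N falls monotonically with import strength; only mid-strength
scores respond strongly to kinase activation (fold > 1.5); blocking export
(LMB column) lowers C/N only where active cycling matters. The round trip in
`examples/02_simulate_and_analyze.py` renders a 2-field Fsk experiment and
recovers the true ratio:

```
 t_min  measured C/N  true C/N
     0         0.676     0.677
     5         0.759     0.759
    10         0.987     0.987
    19         1.015     1.015
```

and `examples/03_response_kinetics.py` summarises an agonist→inhibitor time
course (first significant response 4 min after forskolin, half-maximal at
7 min, collapse to 0.44-fold after H89). The same pipeline is scriptable from
a shell:

```
ktrkit simulate -c config.json -o run/sim
ktrkit analyze  -i run/sim -o run/analysis --roi-mode masks --background-mode mode
```

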