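# Methods

This note records the model equations, the numerical choices, the default
parameterization and its provenance, what the synthetic record does and does
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Hydraulics

The stream network is a single downstream chain of rectangular reaches on a
river-mile axis. Flow routing is quasi-steady: the flow in a cell is the sum
of all boundary and lateral inflows at or above it, so conservation and
confluence addition are exact identities rather than numerical outcomes.
Depth solves Manning's equation, Q = (1/n)·A·R^(2/3)·√S with A = wh and
R = wh/(w+2h), by bracketed root finding (scalar) or safeguarded Newton
(vectorized); residuals are driven below 1e−8 relative. Velocity is Q/A and
bed shear τ = ρ g h S. This replaces a momentum solver deliberately: the
hydrodynamics exist only to hand flows, depths, velocities and shear to the
transport and fate stages. Unsteady wave routing, wetting/drying and lateral
variation are out of scope.

Default geometry is solved so the Manning rating reproduces the intended
base-flow stages: the headwater reach (mile 0–0.8, width 1.83 m, n = 0.055,
S = 2.0e−4) runs ≈ 0.18 m (0.6 ft) deep at its 0.024 m³/s base flow, and
the receiving reach (mile 0.8–3.0, width 4.57 m, n = 0.045, S = 2.9e−4)
≈ 0.27 m (0.9 ft) at 0.184 m³/s. Each reach defaults to 20 equal cells.
Longitudinal dispersion defaults (0.5 and 1.0 m²/s) are assumptions — no
dye-test values are published for the site — and are labelled as such.

## Source loading

Spring sources follow a regime-stratified rating with continuous first-order
decay,

    C(Q, t) = a_regime · (Q/Qref)^b_regime · exp(−λ (t − t0)),

with the storm regime selected above a configured flow threshold. The
functional form is a design choice; only the structure (flow-based rating
plus first-order temporal decline) is given by the problem. The 6%/yr
decline is interpreted as a continuous rate, λ = 0.06/yr, because the
six-year surviving fraction is computed exponentially: e^(−0.06·6) = 0.70
(2 d.p.). Loads are flow × concentration (1 ng/L · 1 m³/s = 86.4 mg/day).
The decay-rate estimator is ordinary least squares on log concentration
against time, optionally with log flow as a covariate to absorb the rating
exponent; the reported standard error is the OLS slope standard error.

A note on recoverability: with lognormal observation error of CV 0.5 and
n = 60 samples spread over five years, the slope standard error is
σ_log/(sd_t·√n) ≈ 0.47/(1.44·7.7) ≈ 0.04/yr — two thirds of the signal
itself. A single monitoring series therefore cannot pin the rate tightly;
the estimator-level recovery check in the test suite averages fits over 100
independent replicate records (standard error ≈ 0.004/yr) and checks that
the fixed-seed single series' 95% confidence interval covers the true rate.

## Fate and transport

One well-mixed water layer per cell; two bed layers (active + deep) of
fixed solid mass. State variables are TSS (mg/L), total water-column PCB
(ng/L) and bed PCB (mg/kg dry). Processes, all first-order in
concentration:

* equilibrium partitioning, f_d = 1/(1 + Kp·TSS), Kp = Koc·foc;
* settling of the particulate phase at v_s and volatilization of the
  dissolved phase at k_v (both as exchange velocities over depth);
* porewater exchange k_f·(C_pw − f_d·C_w)/h with C_pw = C_bed/Kp_bed;
* excess-shear resuspension M_e·(τ/τ_c − 1)⁺, zero below critical shear,
  with deposition probability 1;
* bioturbation as inter-layer mass exchange D_b/Δz·ρ and burial at v_b plus
  the net depositional solid flux (erosional days entrain deep-bed material
  instead, tracked as an external input at the deep-layer concentration).

Numerics: suspended solids use a per-day steady-state ladder (their
residence time is far shorter than a day). The PCB water column advances
with explicit first-order upwind advection and central dispersion at a
sub-daily step chosen to keep Courant + diffusion number ≤ 0.9, with the
lumped first-order losses applied by exact exponential update each sub-step
(this makes the volatilization-only closed cell exact rather than
first-order accurate). On days when the whole-domain hydraulic residence
time falls below 0.25 d (storm days), the water column is taken at its
steady ladder solution; the transition mass is booked into export, and water
arriving or leaving with daily stage changes is booked as explicit
volume-exchange terms. The bed advances daily (its time constants are
years). Every flux is accumulated in grams, so budget closure —
inputs = outputs + Δstorage — is a genuine implementation check; the test
suite requires closure within 0.5% and the scheme achieves round-off.

Because every process is linear in the PCB concentrations and the solids
field is independent of them, superposition holds: single-source runs
(each external load alone, plus a run driven only by the initial bed
inventory) sum to the combined run to machine precision, which is how
diagnostic source apportionment is computed. Nonlinear options do not
exist in this implementation, so the apportionment precondition is
satisfied by construction.

Default fate parameters (Koc = 3.16e5 L/kg OC, foc 0.10 on particles and
0.04 in the bed, v_s = 0.2 m/d, τ_c = 1.5 Pa, M_e = 0.05 kg/m²/d,
k_v = 0.15 m/d, k_f = 0.03 m/d, D_b = 2e−6 m²/d, v_b = 5e−6 m/d, active
layer 5 cm over 15 cm at 1.25 kg/L dry, porosity 0.5) are desk-scale
assumptions: no site-calibrated values are published. They were set to
plausible literature magnitudes and adjusted only so the configuration
reproduces the documented loss-share pattern — settling below 1% and
volatilization a few percent of the annual load delivered to the headwater
stream — and are flagged as assumptions, not calibration results.

## Food web

Benthic invertebrates equilibrate with the organic-carbon-normalized active
bed (β_soc·(C_bed/foc)·lipid), water-column invertebrates with the
dissolved phase (BAF_w·f_d·C_w·lipid), and terrestrial invertebrates are
identically clean — they exist to dilute the contaminated diet. Fish follow

    dν/dt = k_u·f_d·C_w + α_d·I·Σᵢ pᵢ(month)·νᵢ − (k_e + G)·ν,

integrated daily with an exponential update. Growth G comes from the
age–weight power curve w = c·age^p (so G = p/age per year), respiration
from R = α_R w^(−γ) e^(θT), and ingestion closes the energy budget,
I = (R + G)/AE. Diet and lipid switch monthly; elimination is modulated
inversely by the lipid cycle (higher lipid, slower loss), which together
with temperature-dependent ingestion produces the within-year oscillation
seen in monitoring. Age classes 1–3 are simulated as cohorts that shift
down the ladder on each model birthday; the station value is the unweighted
mean over the sampled classes, mirroring composite sampling. Fish are
stationary at their station (home ranges are short relative to reach
lengths). Toxicokinetic defaults (k_u = 300 L/kg/d, k_e = 0.01/d,
α_d = 0.8, AE = 0.8) are literature-plausible placeholders, flagged as
such; k_e is supplied directly rather than derived from Kow to keep the
parameterization flat and testable. Fillet-basis stations apply a single
configurable whole-body→fillet ratio (default 0.35).

## Scenario engine

The treatment facility intercepts a configurable fraction (default 0.85) of
spring flow — the uncaptured remainder models the seeps and collection
losses observed at such systems — treats up to its capacity (450 gpm
default), and spills excess intercepted flow into a fill-spill storage
basin that drains back through the plant as capacity frees. Treatment
removes 99% of PCB mass (assumed; no removal efficiency is published).
Alternative 1 removes the facility; 3 additionally dredges the headwater
bed to the 1 mg/kg cleanup criterion, captures the seep (NSB) flow into the
plant and relocates the outfall downstream; 4–7 escalate storage
(1–13 Mgal) and capacity (600–1000 gpm).

Bounding calibrations shift, in opposite directions, the parameters that
control how strongly the system responds to source control: spring decline
rate (0.04 / 0.06 / 0.08 per yr), storm-regime load (×1.5 / 1 / ×0.7), seep
load (×0.7 / 1 / ×1.3), sediment–water exchange (×1.5 / 1 / ×0.7),
volatilization (×1.1 / 1 / ×0.9, the small compensating adjustment), and a
±0.10 shift of diet from terrestrial to benthic. The magnitudes are
assumptions (the published account gives directions, not numbers) and are
configurable. Because each shift acts monotonically on concentration at all
times, the lower/base/upper fish trajectories bracket pointwise; the tests
verify this numerically rather than assuming it.

Projections recycle the five-year calibration flow record cyclically, so
projection hydrology repeats observed wet/dry sequencing. The post-remedy
delay adjustment multiplies the spring-driven fraction f_adj of each medium
by the surviving fraction e^(−λΔt):

    m = 1 − (1 − e^(−λΔt))·f_adj,

giving 0.70 for the water column (f_adj = 1) and, with the default
station/species fractions (0.6285, 0.5623, 0.3639, obtained by inverting
the reported multipliers), fish factors of 0.81, 0.83 and 0.89. Multipliers
are rounded to two decimals only at reporting.

## Compliance statistics

The statistical unit is the composite analysis (three pooled fish), never
the individual. Nondetects are substituted at half the method detection
limit before any summary. The RCC decision runs two one-sided one-sample
Student's t-tests against the station target at α = 0.05: significantly
below → success, significantly above → failure, otherwise inconclusive.
This two-one-sided-tests reading of the three-outcome clause is an
interpretation (the decree's exact formulation is not public) and is
documented as such. Each station carries its own clause, so no multiplicity
adjustment is applied across stations. Decline from pre-remedy uses a
one-sided Welch two-sample t-test. The implementation computes the t
statistic and Student-t p-values directly; the test suite checks decision
agreement against scipy's independent t-test routines on 1000 random
datasets and verifies the type-I "failure" rate at μ = target stays at α
within Monte-Carlo error.

## Synthetic record

Base flows are AR(1) in log space (ρ = 0.95) with lognormal stationary
distributions; storms arrive as a shared Poisson process (15/yr) whose
pulses decay over 1–3 days with stream-specific lognormal magnitudes driven
by a common shock — a flashy karst hydrograph whose headwater max/base
ratio falls in the hundreds. Spring concentrations are the rating times
mean-preserving lognormal error (CV 0.5); routine monitoring samples only
non-storm days. Fish individuals are lognormal about the station mean
(CV 0.35) and are pooled into composites of three, so composite variance is
about a third of individual variance. The default fixture places stations
at miles 0.6 (CBVP), 1.2 (RCVP) and 2.95 (RC43); initial bed concentrations
are 10 mg/kg in the headwater reach and 0.8 mg/kg downstream; spring rating
600 ng/L at the 0.02 m³/s reference flow with mild dilution exponents
(−0.10 base, −0.15 storm) and a 500 ng/L seep.

What the generator does not emulate: rainfall–runoff physics, congener
patterns, analytical batch effects, fish movement, or the actual site
record — passing tests demonstrate internal consistency and correct
statistical behaviour of the pipeline under known conditions, not agreement
with any real monitoring data.

## Problem sizes

Default runs use 40 cells (20 per reach), daily hydrology, sub-daily
transport only where the residence time requires it, a five-year synthetic
calibration record and ten-year projections; a full projection completes in
seconds and the entire analysis sequence in a few minutes on one CPU. These
sizes were chosen as the smallest that exercise every mechanism (storm
resuspension, bed memory, seasonal fish cycles) without blurring the
qualitative patterns of interest.

## Limitations

Total PCBs as one state variable; no congener chemistry, DOC third phase,
bed armoring, flocculation or temperature-dependent Henry's law; rectangular
channels without floodplain storage exaggerate storm depths; daily
resolution stretches sub-daily storm pulses, likely overweighting storm
exposure of fish relative to an hourly model; the karst groundwater system
behind the springs is represented only by the rating-plus-decay boundary,
and floodplain-soil pathways are recorded in configuration but not
modelled.
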