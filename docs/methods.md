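# Methods

`cardioloop` simulates a single cardiac half-sarcomere through a coupled
excitation–contraction model and uses it to study why the end-systolic
force–length relation (ESFLR) depends on the mode of contraction
(isometric versus afterloaded work-loop), focusing on mechano-calcium
feedback: the force-dependent affinity of Ca²⁺ for troponin-C.

## Model

The coupled system has three components, integrated as one stiff ODE system
(19 states):

**Action potential.** A modified FitzHugh–Nagumo model (Rogers & McCulloch,
1994) with a dimensionless excitation variable `v` and recovery variable `r`:

```
dv/dt = c1 v (v − a)(1 − v) − c2 v r + I_stim(t)
dr/dt = b (v − d r)
```

`v` is mapped affinely to membrane potential, V = −80 mV + 120 mV · v. The
recovery constants were re-chosen (`b` = 35 s⁻¹, `d` = 0.75) so that one
square 2-ms stimulus at 1 Hz elicits exactly one action potential with a
rat-like time course at room temperature (peak ≈ +19 mV, APD₅₀ ≈ 52 ms,
APD₉₀ ≈ 103 ms). No electrophysiological detail (ion currents,
stretch-activated channels) is represented.

**Ca²⁺ handling.** A compact local-control CICR (Ca²⁺-induced Ca²⁺ release)
unit in the architecture of Hinch et al. (2004): an L-type Ca channel (LCC)
and ryanodine-receptor (RyR) release unit coupled through a
rapid-equilibrium diadic subspace. Release units occupy four macroscopic
states (available → LCC-open → releasing → refractory). The LCC activation
gate is an instantaneous sigmoid of V; whole-cell LCC Ca²⁺ entry is the
gate times a GHK driving term. RyR triggering depends on diadic Ca²⁺ (the
cytosolic level plus a boost proportional to the LCC GHK drive while the
LCC is open); an optional regenerative pathway lets cytosolic Ca²⁺ itself
trigger available units through a steep Hill function (disabled in the
default parameterization). The bulk compartments are cytosol and SR, with
SERCA uptake (Hill n = 2), SR leak, a linearized Na⁺/Ca²⁺-exchange efflux,
a constant background influx, a dynamic fast cytosolic buffer, and a
rapid-buffering calsequestrin pool in the SR.

The published local-control model's parameter values were not available for
transcription, so this unit was parameterized once to the rat
room-temperature (≈ 22–23 °C) operating point the study conditions define:
diastolic Ca²⁺ ≈ 0.08 µM, peak ≈ 1.4 µM, time-to-peak ≈ 26 ms, FWHM
≈ 60–90 ms depending on mechanical state, 1-Hz pacing with ≈ 5–6 µM
sarcolemmal Ca²⁺ turnover per beat. Its parameters live in
`src/cardioloop/data/parameters.yaml` with units and provenance notes.

**Myofilaments.** The Rice et al. (2008) approximate model of cooperative
thin-filament activation and three-state cross-bridge cycling, with its
published parameter values and Q10 factors, evaluated at 23 °C. It
comprises Ca²⁺ binding to troponin-C regulatory sites with distinct
off-rates for the low-affinity (no strong cross-bridge, k⁻ = 250 s⁻¹ at
reference temperature) and high-affinity (strong cross-bridge, 25 s⁻¹)
regimes; a nonpermissive/permissive thin-filament switch with steep
cooperativity (n = 15); attachment (f_app), rotation (h_f, h_b) and
detachment (g_app, g_xb) of cross-bridges with strain-modulated rates; and
mean-distortion dynamics that implement shortening deactivation (length
changes drive the mean distortions through ½·dSL/dt). Active force is the
single-overlap fraction times the distortion-weighted strongly bound
fractions, normalized to the maximal steady-state duty ratio. Passive force
is the signed titin element (slack length 1.9 µm); the muscle-level
collagen element is disabled because the model represents a sarcomere, not
a trabecula. Metabolite factors of the thermodynamically constrained
cross-bridge cycle are held at their physiological reference values and
absorbed into the base rates.

**Mechano-calcium feedback.** The fraction of overlap-zone regulatory sites
governed by the high-affinity off-rate equals the strongly bound
cross-bridge fraction relative to its maximal duty ratio. The net
Ca-troponin flux applied to the cytosolic Ca²⁺ balance is the exact time
derivative of the troponin-bound Ca²⁺ under this weighting (including the
overlap and strong-binding weight derivatives), so total Ca²⁺ is conserved
to solver precision when the sarcolemmal fluxes are switched off. Beat
records export the quasi-static net binding flux (`j_tnc`), which is the
physically interpretable binding/unbinding rate. With
`feedback_enabled=False` all troponin sites use the low-affinity kinetics
with no length weighting, making the Ca²⁺ transient entirely blind to
mechanics — the clean ablation of the mechanism.

## Protocols

All protocols pace at 1 Hz for 20 beats (the protocol's steady-state
operating point) and normalize force to the peak total force of the
steady-state isometric twitch at L₀ = 2.3 µm.

* **Isometric**: fixed sarcomere length; ESFLR point = (length, peak force).
* **Work-loop** (four phases, transitions located by event root-finding):
  isometric contraction at L₀ until total force exceeds the afterload;
  isotonic shortening with the force-balance velocity
  dSL/dt = (F_afterload − F_total)/ν until the velocity returns to zero
  (end-systole); isometric relaxation until Ca²⁺ falls within 2% of the
  pre-stimulus diastolic level; constant-velocity restretch to L₀ over
  50 ms. ESFLR point = (end-systolic length, afterload). At afterload 1 the
  shortening threshold is never crossed and the loop is exactly the
  L₀-isometric twitch.
* **Quick release**: a linear length ramp (default 1 ms) from L₀ to
  0.92 L₀ at a chosen time in the twitch, compared with the isometric
  reference from the same pre-beat state (the Ca²⁺-surge protocol).
* **Cross-over**: the work-loop integrated in clamped-Ca mode, driven by
  the periodic cubic-spline playback of the Ca²⁺ transient recorded from
  its force-equivalent isometric contraction (the isometric length whose
  steady-state peak force equals the afterload, found by bisection).

## Numerical choices

* LSODA with relative tolerance 1e-6 and per-state scaled absolute
  tolerances (1e-9 × a magnitude scale per state); dense output; events by
  the solver's sign-change root finding. Halving the tolerance changes the
  peak twitch force by < 0.1% (tested). The 1e-6 default was chosen over a
  tighter setting because convergence is already well inside the 1%
  stability requirement and work-loop batteries run an order of magnitude
  faster.
* Each beat is integrated in segments split at the stimulus-off time and at
  phase-transition events, so the solver never steps across a
  discontinuity.
* The isotonic constraint uses a viscous relaxation constant
  ν = 5·10⁻⁵ (normalized force)·s/µm, small enough that the Phase-2 force
  stays within 10⁻⁴ of the afterload while keeping the ODE well posed.
* Two regularizations of the distortion dynamics are required at room
  temperature (where the Q10-scaled rotation rates are ≈ 13× slower than at
  37 °C): the mean-distortion relaxation coefficients use the strain-free
  rotation rates (the strain-modulated ones can freeze the relaxation of a
  nearly empty strongly bound pool and let the distortions diverge during
  restretch), and the strain-modulation exponents of the population rates
  saturate at ±8 (far beyond the physiological distortion range; reached
  only momentarily during imposed quick-release ramps). Population
  kinetics, strain-dependent detachment and shortening deactivation are
  unchanged.
* Default initial conditions are the 1-Hz paced steady state of the
  L₀-isometric preparation, so trains reach the beat-to-beat criterion
  (peak change < 0.1%) within two beats at L₀. At other lengths the Ca²⁺
  balance re-equilibrates with a slow (tens of beats) time constant;
  after the protocol's 20 beats a residual peak-force drift of up to
  ~0.8%/beat remains at the shortest lengths and is recorded as a warning
  on the result object. ESFLR values are therefore defined at the 20-beat
  protocol operating point.

## Synthetic Ca²⁺ waveforms

`ca_waveforms.make_parametric` builds double-exponential twitch transients
(configurable diastolic level, amplitude, rise and decay constants, offset)
with a closed-form peak time, used to test the clamped-Ca machinery and as
the oracle for the transient metrics; `ca_waveforms.record` captures a
simulated beat for playback. The parametric family emulates the shape of a
twitch transient but none of the mechanisms behind it (no SR depletion, no
feedback, no beat-to-beat memory), so tests built on it validate the
measurement and playback machinery, not the Ca²⁺ biology.

## Measurement conventions

Onsets (of the Ca²⁺ transient and of active force) are the first upward
crossing of the diastolic level plus 5% of the respective amplitude;
transient duration is the full width at half amplitude over diastole
(width_50). The 5% threshold is a robustness choice (it sits above solver
and interpolation noise); moving it to 10% shifts onsets by < 5 ms
(tested). All onset times are reported relative to the beat start (the
stimulus), so delays between onsets are convention-free.

## Known limitations

* The Ca²⁺-handling unit is a surrogate with the right architecture and
  operating point, not a transcription of the published local-control
  parameter set. Its main visible consequence: the mode dependence of the
  Ca²⁺-transient *width* is qualitatively correct (isometric transients
  widen strongly with shorter length, work-loop transients widen with lower
  afterload, and every force-equivalent isometric transient is wider than
  its work-loop partner), but the *late-decline* separation between the
  recorded isometric drive and the work-loop's own transient is small
  (≈ 5–10%). Driving work-loops with the recorded isometric transients
  therefore shifts the end-systolic points leftward by only ~10 nm, and the
  fixed-Ca work-loop ESFLR approaches but does not cross the isometric
  ESFLR within the afterload range 0.2–1. A control experiment with a
  synthetic slow-decay drive (decay constant 0.4 s) moves end-systole by
  150 nm, confirming the protocol machinery itself can express a crossing
  when the drive separation is large enough.
* The quick-release Ca²⁺ surge shows a small late undershoot (≈ 1% of the
  transient amplitude near t = 300 ms) from faster extrusion of the surged
  Ca²⁺; the published traces return to zero without a visible undershoot.
* Temperature is fixed at 23 °C; metabolite sensitivity, stretch-activated
  channels, the slow force response and tissue-level coupling are out of
  scope.
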