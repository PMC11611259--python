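# Methods

This note documents the model as implemented: its assumptions, parameter
provenance, numerical choices, and the places where the design was
genuinely open.

## Afferent transfer functions

GVS current maps to canal-afferent firing-rate change through four linear
transfer functions H_SCC(s) = H_L(s)·H_U(s), one per afferent class
(regular/irregular) × stimulation polarity (cathodal/anodal).  H_L is a
first-order lead-lag (s − z)/(s − p) with unity high-frequency gain and DC
gain z/p < 1: it contributes nothing above ~0.1 Hz and produces the
characteristic onset-then-decay of the DC step response.  H_U is
implemented as a flat per-branch gain (the high-frequency asymptote, in
Δspk/s per mA).  A frequency-dependent H_U could be supplied through the
same config; we use a flat gain because every stimulus in scope (DC and
0.07–0.36 Hz waveforms) lies well below the frequencies where primate
GVS-evoked gain curves bend upward, and any residual scale difference is
absorbed by the trained gain K_GVS.

The numeric coefficients are **this package's own fit**, not published
constants.  No peer-reviewed source prints them; what is published is
behavioral: cathodal (depolarizing) responses exceed anodal, irregular
afferents respond several-fold more strongly than regular and adapt faster
under DC (settling within the 0–40 s range), and sustained responses are
diminished relative to onset.  We therefore fixed the structure above and
calibrated the remaining freedom once against the population-level
quantities the trained model is reported to reproduce — a peak virtual
rotation of ~1 deg/s per mA and a static DC tilt gain of ~1.5 deg/mA at the
trained operating point (K_Reg = 0, K_GVS = 0.0245) — then froze the
result:

| branch | gain (Δspk/s/mA) | z (rad/s) | p (rad/s) | DC/onset | τ (s) |
|---|---|---|---|---|---|
| irregular cathodal | 8.8 | −0.1367 | −0.1667 | 0.82 | 6 |
| irregular anodal   | 6.8 | −0.0867 | −0.1111 | 0.78 | 9 |
| regular cathodal   | 3.0 | −0.0425 | −0.05   | 0.85 | 20 |
| regular anodal     | 2.4 | −0.036  | −0.045  | 0.80 | 22 |

Time-varying currents are routed by half-wave decomposition: the
depolarizing half of the local (per-ear) current drives the cathodal
filter, the hyperpolarizing half the anodal filter, with both filters
integrated continuously so no state resets occur at polarity switches.
This reduces exactly to the separate cathodal/anodal fits for DC and for
half-cycles of slow sinusoids.  Currents above ±1 mA use the same linear
transfer (a deliberate extrapolation; afferent recordings only constrain
±1 mA).  Sign convention throughout: positive current = left cathode /
right anode.

## Canal geometry

The binaural montage is assumed to stimulate the anterior, posterior and
horizontal canals of one ear equally, so one scalar ΔFR(t) per ear scales
the fixed head-frame axis R_y N⁻¹[1,1,1]ᵀ.  The rows of N are the mean
human canal-plane unit normals from the multiplanar-CT anatomy of Della
Santina et al. (2005), re-signed so each row is the rotation axis that
*excites* the canal (right-hand rule: horizontal canal → ipsilateral yaw,
anterior → nose-down pitch + ipsilateral roll, posterior → nose-up pitch +
ipsilateral roll) and mirrored as axial vectors (−x, y, −z) for the left
labyrinth.  R_y is a +7° rotation about the interaural axis aligning the
anatomical (Reid's-plane) frame to the head frame (x out the nose, y out
the left ear, z up; positive roll = right ear down).  With these
conventions a positive DC current yields a net virtual-rotation vector in
the roll–yaw plane with negative roll component, i.e. tilt perception
shifts toward the cathode side — verified end-to-end as a sign property in
the tests, which pinned down the sign/handedness ambiguities the anatomical
tables leave open.

## Fusion

GVS firing-rate vectors convert to angular velocity inside the fusion
stage, using the inverse passband gain of physical canal transduction:
1.85 deg/s per Δspk/s (irregular) and 2.29 (regular).  The physical branch
is already in deg/s and is assumed identical for both afferent channels and
bilaterally symmetric (healthy labyrinths), so the per-ear split of
physical afference is not modeled.  K_Reg ∈ [0, 1] weighs the regular
channel (irregular = 1 − K_Reg); K_GVS scales the whole GVS contribution
and absorbs species, montage, and unit-conversion differences.  Defaults
are the trained values K_Reg = 0, K_GVS = 0.0245.

## Observer

Central processing is the standard observer architecture with the
canonical gain set of the passive-motion lineage: k_ω = 8, k_f = 4,
k_fω = 8, k_a = −4, τ_d = 5.7 s, g0 = 9.81 m/s².  These are exposed in
config and deliberately *not* refit — GVS enters only as peripheral
afference, with the internal models left maladapted to it.  The net GVS
effect on the otolith system is taken as zero (mirrored hair-cell
polarization across the striola), so otolith afference is the true
gravito-inertial force f = g − a.

The implementation resolves the estimates as follows.  The internal canal
model is the same first-order high-pass as the periphery, applied to ω̂
via its low-pass state ĉ.  Both ω̂ and â appear algebraically (no
artificial fast states):

    â  = k_a/(1 − k_a) · (f − ĝ)
    f̂  = ĝ − â
    e_f = (f × f̂) / (|f||f̂|)
    ω̂  = (k_ω(α + ĉ) + k_fω e_f) / (1 + k_ω)
    ĝ̇  = ĝ × (ω̂ + k_f e_f),   ĉ̇ = (ω̂ − ĉ)/τ_d

where α is the fused canal afference.  The rotational otolith conflict e_f
(the axis that rotates the expected GIF toward the sensed GIF, magnitude
sin of the error angle) feeds both the angular-velocity estimate (k_fω)
and the gravity propagation (k_f).  Of the two somatogravic variants in
the literature — vector blend versus rotational-error feedback — we chose
the rotational form for both terms: it preserves |ĝ| exactly in the
absence of conflict, keeps the two pathways dimensionally parallel, and
reproduces the expected phenomenology (velocity storage with effective
time constant τ_d(1 + k_ω) ≈ 51 s; bounded DC tilt; post-offset decay with
two well-separated time constants, ≈1 s and ≈20 s in the roll plane).  ĝ
is not renormalized during integration (a `renormalize_g` flag exists for
numerical hygiene); tilt readout uses direction only: roll = atan2(ĝ_y, ĝ_z),
pitch = atan2(ĝ_x, ĝ_z).

Perceptual reports are treated as delayed/biased/scaled observations of the
model's tilt estimate; no internal perceptual delay is modeled (the ~0.6 s
empirical delay is a reporting artifact handled by preprocessing).

## Numerical choices

All rational transfer functions are discretized by the bilinear (Tustin)
transform; phase error is negligible through 25 Hz at the default
dt = 0.01 s.  The observer integrates with a fixed-step Heun
(predictor–corrector) scheme; halving dt changes the DC roll-tilt readout
by ~1e-4 deg, and |ĝ| drifts by < 1e-6 relative over 30 s of sustained
virtual rotation.  The integration step follows the input time grid.  The
observer core is batched (state arrays (batch, 3)) so Monte Carlo
populations and calibration grids propagate in one pass; 1000 draws of a
30 s paradigm take a few seconds on one core.  State divergence (norm
overflow) aborts with a diagnostic rather than returning garbage.

Grid-search calibration normalizes each cost surface by its own minimum
(+ε) before the weighted joint sum, and ties on a front resolve to the
smallest K_GVS.  The individual-gain fit does one parabolic refinement pass
around the grid optimum.  The SHH gain correction solves its L1 objective
exactly by a weighted median; the delay search is exhaustive on the sample
grid over [0, 3] s; the small-tilt exclusion (|actual| ≤ 2°) applies only
to the gain step, not to bias or delay.

## Paradigm generators

Sum-of-sines roll profiles use three equal-amplitude zero-phase components
("equal power" for equal-duration pure tones), globally rescaled to ±8°,
lasting two periods of the 0.07 Hz component (≈28.6 s), with a
raised-cosine on/off envelope over the first/last half cycle — the standard
smooth choice for a "sigmoidal" ramp whose exact form is not specified.
Coupled GVS waveforms rescale the tilt angle, tilt velocity, or the mean of
the two peak-normalized signals to ±4 mA, with positive coupling delivering
current of sign opposite the physical characteristic.  The quasistatic
pitch paradigm ramps at 1 deg/s by default (slow relative to canal
dynamics; "quasistatic" is otherwise unquantified) and applies the DC
window after a settling pause.  The DC stimulation window defaults to
25 s, matching the time at which the mean DC response peaks.

## Synthetic data: what it does and does not emulate

The generator produces the full 48-trial two-block design (6 motion
profiles × 7 coupling schemes, sham twice) for participants whose latent
parameters are a GVS susceptibility (scaling K_GVS) plus a reporting
channel: raw = perception(t − delay)/gain + bias + additive white Gaussian
noise (default SD 0.5°, chosen to keep recovery nontrivial but feasible;
real report noise is uncharacterized).  The distortion order is the exact
inverse of the correction sequence, so at zero noise preprocessing inverts
it perfectly.  An optional "small-tilt freeze" reproduces the
reported-bar-parking artifact seen in one empirical participant.

What it does **not** emulate: report noise that is correlated in time or
state-dependent, drifting bias, lapses, motion-sickness dropout, or any
perceptual (as opposed to reporting) individual differences beyond the
susceptibility scalar.  Passing recovery tests therefore demonstrates that
the pipeline is self-consistent and statistically adequate for data with
this structure — not that real SHH data satisfy these assumptions.

One structural point matters when interpreting recovery: the empirical
correction procedure references reports to *actual tilt*, but perception
itself undershoots actual tilt (slope ≈ 0.9), so the fitted reporting gain
absorbs that factor and absolute susceptibilities inherit it.  In the full
procedure this cancels because susceptibility is normalized by a trained
K_GVS fit to the same corrected data.  The recovery tests use
perception-referenced corrections where an absolute comparison is wanted.

## Problem sizes used in the tests

Unit and property tests run the observer at dt = 0.01–0.05 s depending on
the accuracy each check needs; cohort-level recovery uses 20 synthetic
participants on the 24-trial single-block design at dt = 0.05 s, and the
calibration-recovery tests use coarse 5 × 5 parameter grids containing the
true values.  These sizes were chosen as the smallest at which each
property is cleanly resolved; all tolerances are stated in the tests.

## Known limitations

* Transfer-function coefficients are calibrated, not measured; any
  application needing afferent-level fidelity should substitute fitted
  coefficients from electrophysiology via the config.
* Linear current→rate transfer is extrapolated above ±1 mA.
* The VOR pathway, visual/proprioceptive cues, active motion, and
  non-mastoid montages are out of scope; otolith GVS effects are fixed at
  zero net.
* The roll readout atan2(ĝ_y, ĝ_z) degenerates as pitch approaches 90°
  (the roll plane nearly contains ĝ), which is also why pitched-back
  postures yield large predicted roll responses; near that pose the
  numbers should be read as qualitative.
* Observer gains are population constants; only K_GVS individualizes.
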