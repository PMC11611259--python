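# gvsim

Simulation of human self-motion and self-orientation perception under
galvanic vestibular stimulation (GVS) combined with passive 6DoF head
motion.

## The problem

Binaural bipolar GVS — a small current passed between electrodes on the two
mastoids — modulates the firing of vestibular afferent neurons: the cathode
side depolarizes (raises firing rates), the anode side hyperpolarizes.
Because the semicircular-canal afferents normally encode head angular
velocity, this modulation is centrally interpreted as a *virtual rotation*,
which in turn alters the brain's running estimate of the direction of
gravity and hence the perception of tilt.  Predicting that perception
quantitatively — for any current waveform, delivered with or without real
motion — is what this package does.  It is intended for vestibular
psychophysicists, sensorimotor modelers, and engineers designing GVS
paradigms (flight-illusion ground analogs, simulator immersion, vestibular
countermeasures).

## The model

The pipeline has four stages:

1. **Afferent dynamics.**  Four rational transfer functions (regular /
   irregular afferent class × cathodal / anodal polarity) map current (mA)
   to firing-rate change ΔFR (Δspk/s), each the product of a low-frequency
   factor H_L(s) = (s − z)/(s − p) — unity gain as s → ∞, DC gain |z/p| < 1,
   so a current step produces an onset response that decays toward a
   diminished sustained level — and an upper-band gain H_U.  Irregular
   afferents respond more strongly and adapt faster than regular ones.

2. **Canal geometry.**  The montage stimulates the anterior, posterior and
   horizontal canals of each ear equally, so the per-ear head-frame virtual
   rotation is α⃗ = R_y N⁻¹ [1,1,1]ᵀ · ΔFR(t), with N the matrix of average
   human canal-plane unit normals (signed as excitatory rotation axes) and
   R_y a 7° alignment rotation about the interaural axis.  Ears combine
   linearly with weights K_R = K_L = 0.5.

3. **Fusion.**  GVS-evoked firing rates convert to angular velocity with
   per-channel gain interpreters (1.85 deg/s per Δspk/s irregular, 2.29
   regular) and add to the physical-motion canal afference:
   α⃗_SCC = K_Reg (α⃗_phys + K_GVS α⃗_GVS^Reg) + (1 − K_Reg)(α⃗_phys + K_GVS α⃗_GVS^Irreg).
   The trained operating point is **K_Reg = 0, K_GVS = 0.0245** —
   irregular-afferent dynamics alone best explain perception.

4. **Observer.**  A central-processing observer compares canal and otolith
   afference with internal-model predictions and corrects its estimates
   (ω̂, â, ĝ) through gain-weighted sensory conflicts (k_ω = 8, k_f = 4,
   k_fω = 8, k_a = −4, τ_d = 5.7 s).  The gravity estimate propagates by the
   internal kinematic model ĝ̇ = ĝ × ω̂, so GVS-altered rotation signals
   drag tilt perception; the somatogravic (k_f) pathway continuously pulls
   ĝ toward the sensed gravito-inertial force, bounding the tilt a
   sustained current can produce.

On top of this sit calibration (grid-search MSE training of K_Reg and K_GVS
against dynamic-trial traces and a static DC constraint), per-individual
GVS-susceptibility fitting, Monte Carlo population prediction
(susceptibility ~ N(1.03, 0.41)), SHH-report preprocessing
(bias/delay/gain), and a synthetic-data generator that emulates the
48-trial dynamic-tilt experiment for pipeline testing.

## Worked example

```python
import numpy as np
from gvsim import (make_dc_paradigm, simulate_trial, peak_gvs_rotation_rate,
                   monte_carlo_prediction, PopulationModel)

rate = peak_gvs_rotation_rate(current_peak_ma=1.0)
print(f"peak virtual rotation: {rate:.2f} deg/s per mA")

current = make_dc_paradigm(amplitude_ma=2.0, t_on=0.0, t_off=25.0, total_s=35.0)
trace = simulate_trial(None, current)
i25 = np.searchsorted(trace.time, 25.0) - 1
print(f"roll tilt at 25 s of 2 mA DC: {trace.roll_tilt[i25]:.2f} deg")

mc = monte_carlo_prediction(None, current, PopulationModel(), n=1000, seed=0)
print(f"population mean peak tilt: {mc.mean_roll[np.argmax(np.abs(mc.mean_roll))]:.2f} deg "
      f"(CV = {mc.peak_cv:.2f}, peak at t = {mc.peak_time_s:.1f} s)")
```

prints

```
peak virtual rotation: 1.00 deg/s per mA
roll tilt at 25 s of 2 mA DC: -2.97 deg
population mean peak tilt: -2.99 deg (CV = 0.39, peak at t = 25.0 s)
```

A +1 mA direct current evokes a peak canal signal of ~1 deg/s of virtual
rotation per mA; processed centrally, 2 mA of sustained current builds up
to about −3° of perceived roll (negative = toward the cathode side) by the
end of a 25 s stimulation, and across a simulated population the spread of
that peak stays at a constant coefficient of variation ≈ 0.4 regardless of
amplitude.

A command-line interface mirrors the library:

```sh
gvsim simulate --config config.yaml --out out/    # perception CSV + summary
gvsim montecarlo --config config.yaml --out out/  # population bounds
gvsim generate --out data/ --n-participants 4     # synthetic SHH dataset
gvsim fit --out fit/                              # synthetic-cohort calibration
```

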