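# Methods

## The detection problem

A knitted piezo-resistive strain sensor at the ankle produces a voltage that
follows sagittal ankle motion during gait: a maximum around each heel strike
(HS), a minimum around heel lift (HL) as the heel leaves the ground, a sharp
rise to a maximum around toe off (TO) driven by pre-swing plantarflexion,
and a trough in mid swing. The package detects HL, TO and the next HS within
one gait cycle (defined by two consecutive heel strikes) from this voltage
alone, given a short calibration against laboratory ground truth.

Ground truth follows the standard laboratory conventions: heel strikes and
toe off are the instants at which the vertical ground reaction force (GRF)
of the respective force platform crosses 5 N (strictly greater-than; first
supra-threshold sample for HS, last for TO), and heel lift is the minimum of
the ankle-angle signal just before toe off — the onset of pre-swing
plantarflexion — after 6 Hz zero-lag Butterworth low-pass filtering, with
the search restricted to the 0.5 s window before TO (covers terminal stance
at normal cadence).

## Signal conditioning

The knit's baseline resistance drifts slowly (viscoelastic creep), so the
sensor voltage is high-passed at 0.3 Hz — low enough to keep the
low-frequency content of walking. Event detection additionally benefits from
a 4 Hz low-pass, so the detection signal is the 0.3–4 Hz band-passed
voltage, with no amplitude scaling (the threshold parameter stays in volts).

The band-pass is realised as a zero-phase brick-wall FFT filter: transform,
zero every bin with |f| outside the band (band edges inclusive, so results
are bit-stable), inverse transform. No tapering or padding is applied; edge
ringing is tolerable because every trial carries ≥ 0.5 s of padding around
the cycle of interest. The operation is exactly linear and idempotent, which
the test suite asserts. One consequence worth knowing: on a T-second trial
the frequency resolution is 1/T, so for T ≈ 2.5 s the only bin below 0.3 Hz
is DC — slow aperiodic drift is attenuated rather than eliminated. The
residual is small relative to the gait waveform and identical in role to
what any short-window high-pass would leave.

The zero-lag Butterworth low-pass is a forward–backward `filtfilt` of a
4th-order design. Endpoint transients are handled by even (reflective)
padding of ~6·fs/cutoff samples — long enough for edge transients to decay
below 1e-6 so that the operation is symmetric under time reversal (a
property the suite checks directly).

Kinematics sampled at 100 Hz are linearly interpolated onto the 1500 Hz
sensor grid before comparison.

## Signal similarity

Per cycle [HS1, HS2), both channels are band-passed at 0.3–4 Hz and each is
scaled multiplicatively to unit peak-to-peak range (no offset alignment —
the band-pass has already removed means). Agreement is summarised by
Pearson's r and by nMAD, the mean absolute sample-wise difference of the
unit-range curves. Subject-level values are arithmetic means over the
available cycles, one per trial. The cycle slice is half-open at the sensor
grid so HS2 is not double-counted.

## The detector and its calibration

Five parameters: a₁ (volts) and a₂, a₃, a₅ (signed seconds), a₄ (> 0 s).
Detection is a forward search from the first heel strike:

1. P₁ = first sample that is rising (strictly greater than its predecessor)
   and exceeds a₁;  HL = P₁ + a₂.
2. First local maximum at/after P₁ (the toe-off peak);  TO = peak + a₃.
3. Advance a₄, then the next local maximum (the heel-strike peak);
   HS = peak + a₅.

A local maximum is an interior sample with x[i−1] < x[i] ≥ x[i+1]; plateaus
resolve to their first sample and endpoints never qualify, making the search
deterministic. Offsets are deliberately in seconds, not % cycle, so the
detector can run on a raw voltage stream with no cadence estimate; they are
typically negative (the sock features trail the physical events), which is
what makes the method retrospective rather than real-time.

Calibration uses the first five trials with ground truth. Per trial, the
toe-off peak is the first local maximum of the detection signal after true
HL, and the heel-strike peak the first local maximum within ±25 % cycle of
true HS2 (the window tolerates timing jitter while excluding the toe-off
peak). The threshold must sit above everything the forward search meets
before the toe-off rise, and below the toe-off peak, so per trial the
candidate is the midpoint between the early-stance maximum (over [HS1, HL])
and the toe-off peak voltage; a₁ is the across-trial mean. The choice is
then verified — P₁ found with a₁ must land on the toe-off rising edge in
every training trial — with a fallback that lowers a₁ in 10 % steps (at
most 5) before declaring **calibration infeasible**. a₂, a₃, a₅ are the
mean anchor-to-event offsets; a₄ is half the mean toe-off-to-heel-strike
peak interval, which clears the mid-swing trough with maximal margin on
both sides. The across-trial SDs of the per-trial offsets are reported as
the parameters' uncertainties in the Results object.

Infeasibility is a first-class outcome, not an exception path: a spurious
early-stance peak rivaling the toe-off peak (seen in shod walking around
30 % gait cycle) leaves no admissible threshold, and the subject is reported
as a dash row. A calibrated threshold that fails on a held-out trial is
given the same verdict.

## Evaluation protocol

Per subject and condition: truth is re-derived from the reference channels
for all ten trials; calibration sees only trials 1–5; events are predicted
on trials 6–10; per event, error % = 100 · (t_true − t_pred) / (HS2 − HS1)
with each test trial's own cycle duration (the natural normalisation when
cadence varies trial to trial). Reported are the mean of |error %| and the
sample SD (ddof = 1) of the signed error % across the five test trials.
Cohort tables carry one row per subject plus an Average over
calibration-feasible subjects; rounding to one decimal happens only at
rendering.

Because the filter cutoffs are absolute frequencies, % gait-cycle errors
are exactly invariant under uniform time dilation only when the cutoffs are
dilated along with the signals; the suite verifies this form of the
invariance.

## The synthetic cohort generator

No recordings of the instrumented sock are deposited, so all evaluation
runs on synthetic cohorts built to the documented signal structure.

Per subject: cycle duration ~ Normal(1.1 s, 0.1 s) truncated above 0.6 s;
sensor peak-to-peak ~ Uniform(0.2, 0.4) V; the waveform is a sum of signed
asymmetric Gaussians (+HS1 at 0 %, −HL at 40 %, +TO at 60 %, −mid-swing at
80 %, +HS2 at 100 % of the cycle — standard normal-gait phases), the toe-off
bump largest, rise widths ~ U(0.045, 0.065) s and fall widths 1.10–1.22×
slower to emulate viscoelastic (hysteresis-like) relaxation. Trials add a
linear plus 0.05 Hz sinusoidal baseline drift, white noise with SD 5 % of
the peak-to-peak range, and independent per-event timing jitter with SD
10 ms (sock-only) or 15 ms (shod), redrawn to preserve a 50 ms ordering
margin; the jittered construction times are recorded as the trial's truth.
GRF channels are smooth stance envelopes (peak 800 N ≈ 1.2 body weight,
an arbitrary constant — only the 5 N crossings matter) whose crossings sit
exactly at the construction events.

The ankle channel shares the template (in degrees, 20° excursion, symmetric
bumps — the joint angle does not inherit the sock's rise/fall asymmetry,
and a symmetric trough keeps the filtered heel-lift minimum where it was
constructed). Sensor/kinematics divergence is governed by one
`kinematic_mismatch` knob in [0, 1] (sock-only subjects draw U(0.05, 0.6),
shod U(0.25, 0.95)) scaling a set of subject-fixed, unit-scale
perturbations drawn once per subject: per-feature lead/lag of the sock
relative to the physical events (SD 55 ms, capped at ±80 ms so features
never reorder), per-feature amplitude modulation (log-SD 0.45, constrained
so the toe-off bump may only grow and the heel-strike bumps shrink at most
modestly — toe-off plantarflexion is the dominant strain feature, and
threshold feasibility should be lost only through the spurious-peak
mechanism), and three smooth sinusoidal distortion components per channel,
expressed in cycle-relative phase so they repeat identically every cycle.
Because these components are repeatable, they lower the sensor–kinematics
similarity without harming detector accuracy — calibrated offsets absorb
any consistent discrepancy — which is exactly the reported behaviour of
subjects whose curves matched the kinematics poorly yet whose events were
predicted accurately. Trial-to-trial divergence (what actually limits
accuracy) enters through a small per-trial wobble of the ankle features
with SD 0.8 · mismatch · jitter.

Shod subjects additionally carry, with probability 0.05, a spurious
early-stance artifact at 30 % gait cycle: a broad bump (1.5× the toe-off
widths, as a shoe roll-over transient) with subject-level magnitude
0.9–1.2× the toe-off bump and trial-level log-normal variability
(σ = 0.25) — so it defeats any fixed threshold on at least some trials,
reproducing the documented shod failure mode.

The bench stretch–relax simulation produces a triangular strain at a given
rate (default 9 mm/s, 9 mm amplitude) and a resistance that is affine in
strain plus a decaying-exponential baseline drift, a velocity-direction
asymmetry term (the hysteresis loop), and noise; 0.3 Hz high-pass filtering
recovers a near-linear strain–resistance relationship, as the
characterisation experiments showed.

Sub-seeds derive from (master seed, subject index[, trial index]) through
`numpy.random.SeedSequence`, so enlarging a cohort never reshuffles
existing subjects or trials.

### What the generator does and does not emulate

It reproduces the documented amplitude range, drift, noisiness, feature
morphology, timing variability, similarity spread and the spurious-peak
failure mode — enough to exercise every branch of the pipeline against
known truth. It does not model the physics of stitch-contact resistance,
marker-based 3D kinematics, double support, step-to-step cadence drift
within a trial, or pathological gait. Passing benchmarks on these cohorts
shows the pipeline is correct and robust under the stated variability; it
does not certify accuracy on real recordings. Two visible consequences:
the synthetic similarity values cluster higher (subject means r ≈ 0.5–1.0)
than the widest observed between-subject spread, because degrading the
kinematic reference further would corrupt the ground-truth definition
itself rather than just the similarity; and toe-off/heel-strike errors run
below the reported ones, because the generator ties the GRF crossings and
the corresponding sensor bumps to the same jitter draw, while in real gait
the force-plate event and the sock feature decouple further.

## Numerical choices

- "Exceeds 5 N" and "rising" are strict inequalities; first/last-sample
  conventions are fixed as above for bit-stability.
- Band edges of the brick-wall filter are inclusive (a bin at exactly
  0.3 Hz or 4 Hz survives).
- Local-maximum plateau ties resolve to the earliest sample.
- Predictions are not clamped into the cycle; a prediction outside the
  recorded signal raises an explicit error.
- Detection runs on the band-passed but amplitude-unscaled voltage by
  default; a `filtered=False` toggle runs it on the raw voltage instead.
- The heel-strike peak search window in calibration is ±25 % cycle around
  true HS2; the heel-lift search window is the 0.5 s before toe off.
- Cohort benchmarks use 20 subjects × 10 trials per condition with the
  default noise profiles; the full two-condition run takes a few seconds.

## Known limitations

- Retrospective only: offsets place events behind the signal features; no
  causal/real-time variant is provided.
- The threshold rule assumes a single dominant toe-off rise; signals with
  competing early-stance peaks are (correctly) rejected rather than
  resolved.
- Heel-lift truth is quantised to the 100 Hz kinematic grid (±5 ms), a
  floor of ~0.45 % gait cycle on per-trial HL agreement.
- The brick-wall filter's drift suppression weakens on short trials (see
  above); trials much longer than the default padding would improve it.
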