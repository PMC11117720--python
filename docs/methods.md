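# Methods

This note documents the models behind `myokitchen`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that matter when reading or extending the code.

## Synthetic surface EMG

Interference-pattern surface EMG is modelled per channel as zero-mean
Gaussian noise band-pass filtered to 20–450 Hz (4th-order Butterworth,
forward–backward), normalized to unit RMS, and amplitude-modulated by the
scripted gesture. Gesture targets are expressed as *envelope* amplitudes
in µV: because the mean absolute value of a Gaussian of RMS σ is
σ·√(2/π) (folded-normal mean), the carrier RMS is set to
`intensity · √(π/2)` so that the downstream linear envelope of a
sustained gesture converges to the scripted intensity. Baseline noise
(default 3 µV RMS, always present) adds to activation in power:
σ(t) = √(baseline² + activation(t)²).

Flexion drives the flexor channel, extension the extensor channel,
co-contraction both, rest neither. Transitions between intensities are
linear ramps (default 100 ms, implemented as boxcar smoothing of the
piecewise-constant target), which avoids discontinuities and emulates
physiological onset. An optional cross-talk fraction (default 0) leaks
each channel into the other for robustness studies.

What this generator does **not** emulate: motor-unit recruitment and
firing statistics, electrode placement and impedance, motion artifacts,
mains interference, amplitude non-stationarity, and fatigue. Passing
tests therefore demonstrate the correctness of the processing and control
chain under idealized amplitude-coded EMG, not performance on recorded
human signals.

Defaults and units: sampling rate 1500 Hz (typical wireless surface-EMG
hardware); carrier band 20–450 Hz (where surface-EMG power lives, and
safely below the 750 Hz Nyquist limit); baseline 3 µV RMS (an order of
magnitude below the smallest practical threshold); gesture intensities in
scripted scenarios are placed at 3× the relevant threshold, comfortably
inside the 20–100 µV range that per-user thresholds span in practice
while leaving decisive margins over window-to-window envelope noise
(≈6–8 % relative standard deviation per 150-sample window).

## Conditioning chain

`lowpass_filter → rectify → envelope`:

* **Low-pass** — 4th-order Butterworth at 500 Hz applied forward–backward
  (zero phase, no group delay). Because filtfilt applies the magnitude
  response twice, the per-pass cutoff is widened by a factor 1.05 so the
  net response keeps ≤1 dB droop at 0.8×cutoff while still attenuating
  ≥20 dB at 1.4×cutoff.
* **Rectification** — elementwise absolute value (full-wave), idempotent.
* **Linear envelope** — moving average of |x| (mean absolute value, not
  RMS) over 100 ms windows evaluated every 100 ms: non-overlapping
  windows, a 10 Hz decision rate, which is a standard myocontrol latency
  and makes one decision window = one commanded motion step. Only windows
  fully contained in the trace are evaluated (no padding), so startup
  transients never reach the thresholds. Envelope timestamps are window
  *end* times: a decision at t uses only samples already acquired.

## Classification and calibration

The dual-threshold rule is a strict-inequality partition (see README
table); amplitudes exactly at threshold read as rest. The classifier is
stateless per window; all debouncing lives in the FSMs, where motion
gestures act per window (level-triggered) and switch/trigger gestures act
once per movement event (edge-triggered). This split is what keeps a held
co-contraction from spinning through states, and it is why per-trial
statistics count flexion/extension in windows (hundreds per manual trial)
but co-contractions in events (tens).

Threshold calibration anchors each threshold just above the channel's
rest ceiling: `T = rest_max + f · (median_active − rest_max)` with
f = 0.3 by default — monotone in both inputs, strictly above rest by
construction, and robust (via the median) to ramp windows inside the
active segment. When splitting a single rest/flexion/rest/extension/rest
recording, `split_calibration_envelope` trims 0.2 s guards at segment
boundaries so activation ramps contaminate neither the rest reference nor
the active statistics; without the guard, the onset ramp can leak ~11 µV
into the last rest window and bias TVF upward.

## Control modes

State cycle orders are X→Y→Z→Gripper (mode 1) and X→Z→PickPlace
(mode 2); both are configuration, not hard-coded truth, since only the
state counts (4 and 3) are fixed by the design. Flexion maps to negative
axis motion and closing, extension to positive motion and opening; in
mode 2 flexion triggers the automatic pick and extension the automatic
place, paralleling the close/open semantics (configurable via
`FsmConfig.pick_gesture`). Mode 3 selects a highlighted menu option by a
rest dwell of 10 consecutive windows (1.0 s, configurable): selection must
be possible using only flexion/extension plus rest, because
co-contraction is defined to have no function in this mode. The
object→destination phase change happens only on the completion callback
(`notify_auto_done`), never from muscle input; a pending automatic action
that turns out to be infeasible is cancelled without a phase change.

## Kitchen world

Coordinates: y vertical, x–z the table plane, origin at table centre,
metres. The robot is a point end effector on prismatic axes with a
parallel gripper; motion is 0.01 m per decision window, aperture steps
0.005 m up to 0.05 m. The workspace extends 0.06 m past the table edge in
x and z — this overhang is what makes dropping an object off the table
possible at all. Grasping uses box-collider semantics: closing within
±0.04 m horizontally and ±0.06 m vertically of an on-table object's
centre grasps it once the aperture reaches its collider width; a grasped
object is rigidly tied to the end effector.

Physics is quasi-static: on release an object settles instantaneously
onto the support below — a free box slot (snapping to the slot centre),
the table top, or, if its centre is beyond the table footprint, it falls
off and is unrecoverable for the rest of the trial. No rigid-body
dynamics, no object–object collisions: the platform tests myoelectric
control, not physics.

The default layout places all coordinates on a 1 cm grid, keeps objects
≥10 cm apart, and puts the apple farthest from the robot's home pose, so
it is the most effortful object under every mode. All geometry is
overridable through `SceneConfig`.

Automatic pick/place execute through the same motion primitives as manual
control (0.02 s per primitive), so workspace clamping and grasp rules
apply identically, and their simulated duration is accounted in trial
time.

## Scripted ideal participant

`oracle_user` plans open-loop: axis distances divided by the motion step
give runs of motion windows; each state switch is one 0.2 s
co-contraction; menu navigation is one 0.2 s gesture per cursor step plus
a selection dwell. Gestures are separated by 0.3 s rests (below the mode-3
dwell) and aligned to 100 ms window boundaries, so with 3×-threshold
intensities every window classifies decisively: a boundary window carries
at most 12.5 % of the gesture amplitude (≈0.4× threshold) and an interior
window at least 87.5 % (≈2.6× threshold), margins of many standard
deviations of window envelope noise. This is what makes closed-loop runs
deterministic in outcome across seeds, including with baseline noise
raised to 50 % of the smallest threshold.

## Sessions, metrics, limits

A session runs one trial per protocol entry (default 3 modes × 5 objects,
fresh world each), with a 20 s simulated inter-trial pause, so total
session time strictly exceeds the sum of trial durations. Trials fail by
timeout (default 600 simulated seconds — generous next to the ~20 s oracle
trials), by the target object falling off the table, or by trace
exhaustion (counted as timeout); errors alone never abort a trial.
Success rate is successes/trials × 100. Biofeedback is rendered as
structured text (state, AVF/AVE, green band iff amplitude strictly
exceeds the threshold, trajectory trace in mode 1 only); plotting is left
to the caller.

Known limitations: open-loop oracle planning assumes the default
quasi-static world (a physics-rich world would need replanning);
amplitude-only EMG realism as listed above; no simultaneous multi-axis or
proportional control; no human-behaviour model — per-trial counts from
oracle runs are *floors*, not predictions of human effort.

Problem sizes used in the test and acceptance runs — 15 closed-loop tasks
per condition, 10–20 seeds for stochastic checks, a 200×200 amplitude grid
over 8 threshold pairs, 10,000-step command fuzzing — were chosen as the
smallest sizes at which each property is meaningfully exercised; the full
suite runs in seconds.
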