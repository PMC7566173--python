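# Methods

This note documents the simulator's model, its numerical machinery, the
design choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Task environment

The environment is a discrete-event reconstruction of the line-following
task.  A course is a vertical chain of 48-px-high straight segments with
angles drawn uniformly from {30, 45, 90, 135, 150} degrees (90 vertical,
<90 sloping right, >90 left, so the set is mirror-symmetric); a candidate
angle whose segment would leave the admissible horizontal range is
resampled.  Geometry is real-valued throughout — the horizontal run of a 30
or 150 degree segment is the irrational 48*sqrt(3) — and pixel rounding is
a rendering concern the simulator never performs.  Corner goals sit at every
angle-change junction plus the course endpoints; the optimal path is the
polyline through the goals, which with a goal on every corner coincides
with the drawn centerline.

Timing constants are the task's published ones: 24 px/s scroll, 48 Hz
command sampling (0.5 px of scroll per command), 40 ms screen updates,
40 s trials.  The command period is taken as exactly 1/48 s, which makes
the task's printed maximum of 2 px of vehicle motion per scrolled line
pixel exact.  Each left/right command independently succeeds with
probability Ca (auto) or Cm (manual) and moves the vehicle 1 px, clamped to
the screen.  The on-line predicate — |vehicle - line| <= vehicle radius +
line width / 2, boundary inclusive — is evaluated at frame boundaries and
is both the performance score and the warning bit available to perception.
Screen geometry (300 px wide window, 10 px vehicle radius, 5 px line) is
not published for the original environment; the defaults are plausible
reconstructions and are configuration parameters.

Course y is measured in the vehicle row's frame: the row's course ordinate
equals the scroll offset, zero at trial start.  The vehicle starts centered
on the line.

## Clock and scheduling

All events run on an integer clock of 1/1200 s units, on which every
canonical period (1/48 s, 40 ms, 50 ms rule firings, 50/100 ms motor
phases) is exact; event times therefore never accumulate floating-point
error and a trial is exactly reproducible from its seed.  Simultaneous
events dispatch in a fixed priority order — commands, then frame updates,
then motor completions, then rule effects — with insertion order breaking
remaining ties.  Two interchangeable drivers execute the schedule: a
heap-based event-driven scheduler (default) and a deliberately naive 1 ms
fixed-step driver that linearly scans the pending list.  The suite requires
their traces to agree event-for-event on a toy trial, a structural check
that no handler depends on the scheduling data structure.

Configured durations must sit on the clock grid (checked to 1e-9 s);
arbitrary off-grid motor times are rejected rather than silently rounded.

## Cognitive model

Eleven production rules implement a perception-action cycle with
architecture timing: every selected rule's effects apply 50 ms after
selection; visual-location reads are free.  FindVehicle reads the vehicle
position and triggers the reward; FindGoal reads the x of the nearest
upcoming corner goal (smallest positive vertical distance ahead).  In auto
mode KeepA (clear the buffer and loop) competes with ToManual; in manual
mode the five motor rules' conditions partition the (goal position, held
key) space — ToLeft/ToRight start holding a key when the goal is beyond a
2 px alignment tolerance and no key is held, LtoS/RtoS release a held key
whose direction is no longer needed, KeepM covers the rest — so exactly one
of them applies at a time and competes with ToAuto.  The partition reading
matters: if KeepM competed against an applicable steering rule on utility,
a noiseless argmax could permanently lock out a correct steering direction
once its utility dipped below KeepM's, collapsing manual control to chance
drift; under the partition, utilities govern only the genuine decision —
keep operating the current mode or switch.  The 2 px tolerance equals the
vehicle's maximal displacement per scrolled pixel.

Mode switches are fully embodied: the switch rule releases any held keys
through the motor module, PressSpace then punches the space bar, and the
mode flips when the press completes (~0.3-0.5 s end to end).  Motor
requests queue FIFO and are never dropped; preparation (50 ms) is skipped
when a movement repeats the previous one; execution is 100 ms.  Exact
original motor parameters are not published; these defaults mimic
punch-style timings and are configurable.  Rule conditions consult the
motor module's *target* key state (including queued requests) so an
in-flight press is not issued twice.

Conflict resolution adds independent logistic noise of scale `s` to each
eligible utility and takes the argmax; `s = 0` (the studied setting) is
exact argmax with uniform random tie-break.  The closed-form description is
the softmax with temperature sqrt(2)*s; numerically the noisy-max deviates
from it by at most ~0.01 near utility gaps of 2s and <0.005 for gaps below
0.5s, which is why the suite's frequency checks use small gaps.  The
denominator sums over eligible rules only.

Utility learning applies U <- U + alpha(R - U) once per reward event to
every rule that fired since the previous reward, then clears the log; a
rule that fired in one mode can thus be credited by the first reward of the
other mode, the cross-mode bridge that lets switch rules learn the
consequences of switching.  ACT-R's official variant additionally subtracts
the elapsed time since each rule's firing from its reward; that is
implemented behind `time_discount_in_propagation` (off by default, matching
the plain delta rule).

Rewards: the default scheme pays 10 on line, 0 off line.  The SMDP scheme
sums reward over the irregular inter-reward interval — on line,
MaxVehicleSpeed (48 px/s) times the subjectively estimated interval; off
line, the absolute displacement since the last reward (the vehicle position
at the previous reward is kept in the goal buffer).  The interval estimate
comes from a temporal module that is exact by default (keeping SMDP rewards
reproducible); ACT-R-style geometric ticks (start 0.011 s, multiplier 1.1,
logistic tick noise b = 0.015) are available behind a flag.  The reference
position updates at every reward trigger regardless of scheme so schemes
can be switched mid-experiment.

Gating: self-confidence SC and trust T are live aliases of the KeepM and
KeepA utilities.  In gating variants ToAuto is eligible only when SC <= T
and ToManual only when SC >= T (inclusive; at equality both switches are
possible and ordinary conflict resolution decides).  Because KeepM fires
only in manual episodes and KeepA only in auto episodes, SC moves only
while the manual mode is exercised and T only while auto is — the
mode-local bookkeeping the gate needs.

## Experiments and statistics

The study design is a 5x5 factorial sweep of Ca, Cm over {0.3 ... 0.7} with
many independent 40 s trials per cell (500 in the headline runs; the heavy
suite checks use 200 per condition and the acceptance script 100, sizes
chosen so a full sweep of all four variants completes in minutes on one
CPU while leaving per-cell standard errors a few percent).  Per-trial seeds
derive deterministically from (master seed, Ca, Cm, run index), so cells
are reproducible in isolation and sweep order is immaterial.  Baselines:
the bare auto controller run alone, and the cognitive model with ToAuto
removed (manual only), 500 runs per level.

Fit to a reference grid of per-condition means uses R^2 = squared Pearson
correlation over the 25 paired means and RMSE, computed per behavioral
index; zero variance in either vector makes R^2 undefined (reported as
such, never as 0).  The participant means behind the original study are
unpublished, so the package ships a synthetic reference generator with
configurable monotone trends (performance up both axes; auto use up in Ca,
down in Cm; switches down both) plus optional Gaussian noise.  Fits against
it exercise the machinery only; they say nothing about human data.

## What the simulations show

At the study's parameters (alpha 0.2, egs 0, U0 5, reward 10/0) the
simulator reproduces, from mechanism alone: auto-only performance rising
steeply in Ca (≈0.40 to 0.88) and beating the manual-only model at every
matched capability; manual-only performance rising in Cm (≈0.37 to 0.63);
auto use rising strongly in Ca and falling strongly in Cm for the SMDP
variants, with the default-rewarding variants several times less sensitive
to Cm (the mechanistic point of the time-summed rewards: the off-line SMDP
reward scales with how far manual commands actually moved the vehicle,
importing Cm into the utilities); and switching declining as capability
rises, most cleanly in Ca.

One known limitation: the model's own manual skill tops out well below the
auto controller (the perception cycle is 150 ms and key changes cost
150-250 ms, against a 48 Hz controller with no such lags), so at high Ca
the performance surface flattens — and can dip slightly — as rising Cm
draws the model into manual mode.  Mean performance therefore correlates
with Ca+Cm at Spearman rho ≈ 0.76 over the grid rather than rising cleanly
along both axes; human operators, whose high-capability manual skill
approaches the automation's, show the cleaner joint rise.  This is a
structural property of architecture-timed manual control, not a tuning
artifact; closing it would require softening the published timing
constants.  Relatedly, the model switches modes more often than people do
(tens of switches per trial in the noisier conditions).

The synthetic-data path emulates the *shape* of the empirical surfaces, not
their values; passing fit-machinery tests against it demonstrates the
statistics are computed correctly, not that the model fits human data.
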