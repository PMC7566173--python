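# linefollow

A discrete-event simulator of **how operators adapt to imperfect automation
in a time-critical tracking task**, driven by a production-system cognitive
model whose reliance on automation is learned online by reinforcement.

## The problem

In the *line-following task* an operator steers a vehicle left/right so that
it stays on a line scrolling down at 24 px/s.  Steering commands are sampled
at 48 Hz; each left/right command moves the vehicle 1 px, so at best the
vehicle covers 2 px per scrolled line pixel.  The screen (and an on/off-line
warning) updates every 40 ms.  Two control modes are available, toggled with
the space bar: an automatic controller that steers toward the optimal
(corner-to-corner) line, and manual arrow-key control.  Commands succeed only
with probability **Ca** (auto) or **Cm** (manual) — the capabilities of the
two modes, which the operator cannot observe directly and must learn from
experience.  Trials last 40 s; behavior is summarized by three indices:

* **performance** — fraction of 40 ms frames with the vehicle on the line,
* **auto use ratio** — fraction of trial time spent in auto mode,
* **number of switches** between the modes.

The empirical pattern this simulator addresses: performance rises with both
capabilities, auto use rises with Ca and *falls* with Cm, and switching
falls as either capability rises.

## The model

The operator is modeled as a production system with cognitive-architecture
timing: 11 condition–action rules fire every 50 ms against buffer contents,
perception (vehicle position, nearest upcoming corner goal) is a zero-delay
visual-location read, and key presses pass through a motor module with
preparation (50 ms, skipped for repeated movements) and execution (100 ms)
phases.  Rule choice is conflict resolution over learned utilities

    P(i) = exp(U_i / (sqrt(2) s)) / sum_j exp(U_j / (sqrt(2) s))

realized as noisy-max (logistic noise, scale `s`; with the default `s = 0`,
exact argmax with uniform tie-break), and each reward R updates every rule
that fired since the previous reward by the Q-learning delta rule

    U <- U + alpha (R - U)        (alpha = 0.2, U0 = 5)

Rewards are triggered by the perception rule each cycle.  Two mechanisms are
switchable, giving a 2x2 family of model variants:

* **rewarding** — `default`: a fixed 10 on line / 0 off line; `smdp`: the
  reward sums over the irregular interval since the last reward
  (semi-Markov): on line `48 px/s x estimated interval`, off line the
  vehicle's absolute displacement, so reward mass is balanced across rules
  that fire at different rates;
* **conflict** — `default`: mode-switch rules compete freely; `gating`: a
  gate compares self-confidence **SC** (the utility of the KeepM rule)
  against trust **T** (the utility of KeepA) and permits switching to auto
  only when `SC <= T`, to manual only when `SC >= T`.

The full model is the `Gating-SMDP` variant.

## Worked example

One trial per direction of the capability asymmetry:

```
$ linefollow simulate --rewarding smdp --conflict gating --ca 0.7 --cm 0.3 --seed 7
model          Gating-SMDP
performance    0.872
auto_use_ratio 0.953
n_switches     3

$ linefollow simulate --rewarding smdp --conflict gating --ca 0.3 --cm 0.7 --seed 7
model          Gating-SMDP
performance    0.674
auto_use_ratio 0.161
n_switches     6
```

With strong automation and weak manual control the model learns within a
trial to rely on automation (95% auto use); with the asymmetry reversed it
abandons automation and steers by hand (16% auto use).  Performance tracks
the better mode's capability in both cases.

Other entry points: `linefollow baseline` (auto-only controller and
manual-only model capability sweeps), `linefollow grid` (any or all of the
four variants over the 5x5 Ca x Cm grid, 25 conditions), `linefollow fit`
(per-index R^2/RMSE of a sweep against a reference grid of per-condition
means), and `--trace-out` to dump a full JSON-lines event trace of a trial.
Reference behavioral grids are external inputs; `linefollow.synth_reference`
generates a synthetic stand-in grid with the qualitative trends above for
exercising the fit machinery.

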