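# Methods

## Model and assumptions

The excess waiting list is treated as a single national compartment
W(t) with two outflows: treatment through *surplus* capacity T_e
(procedures/year above the pre-pandemic baseline) and death at a
constant instantaneous hazard μ (1/year):

    dW/dt = −μ W − T_e,    W(0) = W₀.

The baseline throughput rS0 + rT0 is assumed fully consumed by the
steady-state inflow of new patients, which therefore cancels out of the
excess-list dynamics; backlog and incident patients are
indistinguishable. Solving the ODE gives

    W(t) = (W₀ + T_e/μ) e^(−μ t) − T_e/μ,

zero at the clearance time t_c = ln(1 + W₀ μ / T_e)/μ, with cumulative
deaths m(t_c) = W₀ − T_e t_c (treatment accounts for T_e t_c patients and
the rest of the backlog died). The model is defined only up to clearance;
the trajectory is truncated at zero afterwards. With T_e = 0 the list
never clears and deaths grow as W₀ (1 − e^(−μ t)).

Key modelling choices:

- **μ is used directly as an exponential hazard.** The published 36%
  one-year mortality is applied as a rate of 0.36/year, not converted via
  −ln(1 − 0.36) ≈ 0.446. Both conventions are defensible readings of a
  "1-year mortality of 36%"; the direct-rate convention is the one under
  which the package's outputs agree with the scenario outcomes it is
  designed to reproduce, and the Euler and patient-level oracles confirm
  the internal consistency of that choice.
- **Year = 365 days exactly.** All day-denominated outputs divide annual
  rates by 365.
- **No re-entry, ramp-up or inflow shocks.** Surplus capacity is constant
  from day one; survivors do not rejoin the list; centre-level
  heterogeneity is out of scope.

## Surplus-capacity arithmetic

Two levers:

- a *general* increase, fraction c of throughput;
- *conversion* of a fraction p of SAVR cases to TAVI at a
  time-equivalence ratio a:b (b TAVI in the time of a SAVR; default 2:3,
  sensitivity ratios 3:4, 2:4, 3:5, held as exact rationals so b/a never
  drifts). A converted patient still occupies one slot, so each converted
  case frees b/a − 1 slots: conv = p · rS0 · (b/a − 1).

Combined, the general increase applies to the **post-conversion** mix:

    T_e = conv + c (rS0 + rT0 + conv).

The alternative (applying c to the pre-conversion mix) differs by the
interaction term c·conv and does not reproduce the combined-scenario
outcome; the post-conversion convention is also the natural reading of
increasing capacity "at that mix". Short-term policy caps p ≤ 0.5 and
c ≤ 0.5 are enforced softly — exceeding them warns rather than errors,
because doubling capacity (c = 1) is itself an explored scenario — with
an `allow_above_cap` flag to silence the warning.

## Uncertainty propagation

W₀ ~ N(4989, 494.65²) and μ ~ N(0.36, 0.12245²), independent, with the
standard deviations unpacked from the 95% CIs as half-width / 1.959964
(the exact normal quantile; 1.96 would differ only cosmetically). Draws
below a floor — 0 for W₀, 1e-4/year for μ — are rejection-resampled,
i.e. the distributions are truncated normals. P(μ < 0) ≈ 0.16% under the
untruncated normal; the closed form is undefined or non-clearing there,
and resampling preserves unimodality while moving the means far less than
reporting precision. A floor of 1e-2 instead of 1e-4 changes the +20%
scenario mean by well under a day.

Each of the default n = 10 000 draws is pushed through the closed forms;
outcomes are summarised by the mean and the empirical 2.5/97.5
percentiles (a 95% **reference range** of the outcome distribution, not a
CI of the mean), using NumPy's default linear interpolation between order
statistics so ranges are bit-reproducible given the seed. The default
seed is 20220616; any seed reproduces the means to Monte-Carlo error
(standard error of the +20% clearance-time mean at n = 10⁴ is ≈ 0.6
days). Because t_c is convex in (W₀, μ), MC means sit a few days above
the point estimates (Jensen gap) — e.g. 534.7 vs 531.6 days for +20%.

What the sampler does *not* emulate: correlation between W₀ and μ,
non-normal uncertainty, uncertainty in rS0/rT0 or in the conversion
ratio, and any real-world time variation in capacity. Passing tests show
the propagation machinery is correct under the stated distributions, not
that those distributions describe the true epidemiology.

## Planner numerics

Grids evaluate outcomes over the (p, c) plane; in `mc-mean` mode one
fixed draw set is reused for every cell (common random numbers), so the
surfaces are strictly monotone along both axes and inverse problems are
well-posed. The zero-surplus corner (p = c = 0) never clears; it carries
an infinite clearance time and, as a severity marker, the one-year
zero-surplus death toll, rather than aborting the grid.

Inverse operations (capacity for a deaths target, capacity for a
clearance-time target) bracket c in [0, c_max] (default 1.0), verify the
target lies between the outcomes at the bracket ends (otherwise a
bracket error reports the attainable range), and solve with Brent's
method to an x-tolerance of 1e-6. When p = 0 the lower bracket is nudged
to 1e-9 because c = 0 leaves zero surplus; outcomes are continuous in
that limit (deaths → W₀, time → large but finite). Isoclines are traced
by per-column root finding in c at each p on the axis — not by marching
squares — so every returned point can be independently re-evaluated;
p values where the level is unattainable are skipped.

## Verification oracles

- **Deterministic Euler**: W ← W − (μ/365 · W + T_e/365) · h in days,
  first-order convergent; the clearance time is located by linear
  interpolation inside the crossing step, and deaths follow from the
  scheme's exact conservation W₀ − W − treated (identical to summing
  μ/365 · W · h). At h = 0.001 day it agrees with the closed forms to
  better than 0.1% over a 5×5 (W₀, T_e) grid.
- **Stochastic patient queue**: integer patients; each day every waiting
  patient dies with probability 1 − e^(−μ/365) (deaths applied before
  treatment — the ordering shifts tallies by O(step) and is fixed for
  reproducibility), then ⌊banked slots⌋ patients are treated, with
  fractional daily slots accumulating so no capacity is wasted.
  Conservation treated + died + waiting = W₀ holds exactly per
  replicate; 200-replicate means match the deterministic deaths within
  3%.

## Problem sizes and tolerances

Defaults: n = 10 000 MC draws per scenario summary (≈ milliseconds,
vectorised); the Jensen-gap check uses n = 10⁵; Euler verification uses
step 0.001 day over horizons up to 2000 days; the stochastic oracle uses
200 replicates. Scenario means are checked against their published
values at ±1% or ±5 units, whichever is larger — the published abstract
and results themselves differ by one unit (535 vs 536 days) for the same
scenario, indicating seed-level wobble at exactly this scale; the
results-section values are the ones targeted. Root-finding tolerances:
c to 1e-6; contour points re-verify to 0.1 day / 0.5 person in
point-estimate mode.

## Known limitations

Single national queue (no centre-level heterogeneity or geography); no
TAVI demand growth; no post-procedural resource constraints (ICU,
length of stay); no clinical prioritisation within the list; mortality
hazard constant in waiting time and age. One published scenario value
(the 30%-conversion clearance time) is mutually inconsistent with its
companion mortality figure under the model's own accounting identity
m = W₀ − T_e t_c; the package reproduces the value consistent with that
identity, and the corresponding check documents the discrepancy.
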