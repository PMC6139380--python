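# Methods

## Model

The simulator implements a discrete-time stochastic map, not an SDE.
One process evolves on the tilted quartic potential
V(x; k) = k·x − x²/2 + x⁴/4, whose gradient is V′(x; k) = k − x + x³.
For |k| < 2/(3√3) ≈ 0.385 the drift −V′ has two stable zeros (the
wells) separated by an unstable one (the saddle); beyond that fold a
single well survives.  The sign convention is fixed throughout:
negative x is the egocentric pole, positive x the other-centric pole,
so positive tilt k deepens the egocentric well.

The single-process update is

    x(t+1) = x(t) + (−k + x − x³) + σ·ξ,  ξ ~ N(0, 1),

i.e. unit descent rate.  The two-process model scales each process's
gradient by its own rate u and adds linear attraction toward the other
process:

    x_P(t+1) = x_P − u_P·(k_P − x_P + x_P³) + α·(x_S − x_P) + σ·ξ_P
    x_S(t+1) = x_S − u_S·(k_S − x_S + x_S³) + β·(x_P − x_S) + σ·ξ_S

Conventions that the equations alone do not pin down, fixed here once:

* **Synchronous update.**  Both right-hand sides read the time-t state;
  there is no sequential leakage.  With α = β = 0 the fast coordinate
  of the 2-D map is exactly the u-scaled 1-D iteration (a tested
  invariant).
* **Noise.**  One independent standard-normal draw per process per
  step, both scaled by the shared σ.  Draws are arguments of the step
  functions, so the maps are deterministic given the draws.
* **Rate placement.**  The descent rate u multiplies only the gradient
  term; the coupling term is added outside it, exactly as the update is
  written above.  u = 1, α = β = 0 recovers the single-process update.
* **Within-trial constancy.**  Tilts do not drift within or across
  trials.  Slow across-trial strategy strengthening is a known
  extension of this model family and is deliberately out of scope; the
  parameter structure (a tilt per process) leaves the hook open.

## Decision rule

A trial starts exactly at the saddle (0, 0) — "near the saddle" is
implemented with no initialization jitter; the first noisy step
provides the perturbation.  Signed accumulators Σx_P and Σx_S start at
0 and add each post-update coordinate (the initial state is not
summed).  The trial stops at the first step where max(|Σx_P|, |Σx_S|)
≥ threshold (default 30).  The crossing accumulator is the winner; its
sign gives the outcome (negative = egocentric).  If both cross on the
same step the larger magnitude wins, with exact ties going to the fast
process — deterministic, and vanishingly rare at the default σ.  The
absolute-value test is a choice: an egocentric settle terminates at
−30, mirroring the other-centric +30.  Trials are capped at
max_steps = 50,000 with an explicit non-decision outcome, which makes
the noise-free exact-saddle case terminate.

These conventions matter for exact regression values: with the
fast-dominance preset and σ = 0 the trial decides egocentrically in
exactly 35 steps with final fast accumulator −30.668276 (pinned in the
tests against a brute-force re-iteration).

## Parameters and presets

| name | meaning | default |
|------|---------|---------|
| k_P, k_S | landscape tilt per process (dimensionless) | preset-specific |
| u_P, u_S | descent rate per step, in (0, 1] | preset-specific |
| α | fast ← slow coupling strength (≥ 0) | 0 |
| β | slow ← fast coupling strength (≥ 0) | 0 |
| σ | per-step noise sd | 0.01 |
| threshold | accumulator bound | 30 |
| max_steps | trial cap | 50,000 |

The four presets are the published regimes: `fig2` (symmetric,
uncoupled, u_P = u_S = 0.2: equibias), `fig3` (k_P = 0.2, u_S = u_P/2:
fast egocentric dominance), `fig4` (k_S = −0.2, α = 0.2: other-centric
strategy dominance), `fig5` (k_S = −0.025, α = 0.2, β = 0.01: mixed,
mutually reinforced responding).  All presets carry σ = 0.01.  The
regime definitions are inconsistent about the equibias noise level
(σ = 0.01 in the parameter table, σ = 0.1 in the accompanying figure
text); the preset uses the table value and σ is exposed everywhere so
either can be requested — the equibias conclusion holds at both
(tested).  One further documented discrepancy: the parameter table
lists β in the fast-process column and α in the slow-process column,
while the update equations place α in the fast-process update; this
package follows the equations, and the choice is corroborated by
behavior — only with α acting on the fast process does the
strategy-dominance regime produce other-centric responding.

A measured caveat about the coupled regime: with this decision rule,
switching the mutual coupling on does *not* shorten mean
time-to-decision relative to the same parameters uncoupled (≈ 58 vs
≈ 35 steps at σ = 0.01, n = 1000), because α attaches the
race-leading fast process to the lagging slow one.  The often-expected
"coherence makes decisions faster" intuition therefore fails here as
measured by first accumulator crossing; the corresponding acceptance
test records this honestly and fails by construction.

## Landscape analysis

The vector field is the one-step displacement of the noise-free map on
a grid (default [−1.5, 1.5]², 21 points per axis, covering all
attractors for |k| ≤ 0.3).  The displacement, not a continuous-time
flow, is what the model defines.  Fixed points are found by multistart
root-finding (scipy's hybrid Powell method seeded from every grid
node, analytic Jacobian), deduplicated at 1e−5 (roots of the cubic are
> 0.5 apart in the relevant range), sorted on coordinates rounded to
1e−6 so root-finder jitter cannot reorder them, and classified by the
eigenvalue magnitudes of the map Jacobian

    [[1 − u_P(−1 + 3x_P²) − α, α], [β, 1 − u_S(−1 + 3x_S²) − β]]

relative to 1 (discrete-map stability): both inside the unit circle ⇒
stable, both outside ⇒ unstable, mixed ⇒ saddle.  Magnitudes within
1e−6 of 1 trigger a warning rather than an error.  1-D equilibria come
from the cubic's roots (numpy companion-matrix roots, cross-checked in
the tests against grid-bisection), with stability from the drift
derivative sign (1 − 3x² < 0 ⇒ stable).

## Randomness and reproducibility

All randomness flows from numpy `SeedSequence`.  A batch with seed s
spawns one child stream per trial from (s, trial index), so batches
are bitwise reproducible and trial i's stream does not depend on how
many trials run before it.  Sweeps spawn one child per parameter value
the same way.  Output files embed the resolved configuration, seed and
package version as a JSON comment header; the run timestamp goes to
the stderr log only, never into files, so identical invocations
produce byte-identical outputs.

## What the simulations do and do not show

Everything here is self-generated synthetic data: the generator *is*
the model, so tests demonstrate internal consistency (the regimes
follow from the equations) and reproducibility, not empirical
adequacy.  No empirical mouse-tracking or choice data is fitted;
response-time distributions are step counts of an abstract map with no
calibrated time unit; and the qualitative regime signatures (equibias,
dominance, mixed responding) are properties of four hand-picked
parameter points, not of the parameter space at large.  Batch sizes in
the tests (50–2000 trials) were chosen so that binomial 3-standard-
error bands make the qualitative verdicts sharp.

## Known limitations

* The state space is unbounded; for |k| ≤ 0.3, σ ≤ 0.1 trajectories
  stay within about [−2, 2], but extreme parameters can escape the
  quartic's basin in one step.
* Stability classification at a fold (|k| near 2/(3√3)) is marginal
  and only warned about.
* The trial engine is a per-trial Python loop with chunked noise
  generation — fast enough for 10⁵-trial studies, not for 10⁸.
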