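# doublewell

A simulator for two-timescale perspective-taking decisions on a tilted
double-well landscape.

In dialogue, people settle on either their own (egocentric) or their
partner's (other-centric) perspective, and they do so through the
interplay of a fast, shallow, automatic process and a slow, strategic,
deliberative one.  This package implements a minimal dynamical model of
that interplay for computational cognitive scientists who want to
explore, extend, or test it: two coupled stochastic processes descend a
tilted double-well potential at different rates, and an
accumulator-threshold rule turns their trajectories into discrete
decisions, drift-diffusion style.

## The model

Each process carries a perspective coordinate *x* (negative pole =
egocentric, positive = other-centric) on the potential

    V(x; k) = k·x − x²/2 + x⁴/4

whose two wells are the stable perspectives and whose tilt *k* biases
one of them (positive *k* favors the egocentric well).  The fast
process x_P and the slow process x_S update synchronously:

    x_P(t+1) = x_P − u_P·V′(x_P; k_P) + α·(x_S − x_P) + N(0, σ)
    x_S(t+1) = x_S − u_S·V′(x_S; k_S) + β·(x_P − x_S) + N(0, σ)

with V′(x; k) = k − x + x³.  The rates u_P > u_S make the first process
faster; α pulls the fast process toward the slow one (top-down
influence of an established strategy), β the reverse.  A trial starts
at the saddle (0, 0) and maintains the running sums Σx_P and Σx_S; the
first sum whose magnitude reaches the threshold (30) decides the trial
— its sign gives the perspective, and the process it belongs to is the
trial's "winner".

Four canonical parameter regimes (`fig2` … `fig5`) are built in as
presets; see `doublewell presets` and the module docs in
`doublewell.experiments`.

## Worked example

Replicate the regime in which a slowly established other-centric
strategy, coupled top-down into the fast process (α = 0.2), overcomes
the fast process's egocentric tilt:

```
$ doublewell replicate fig4 --n 500 --seed 1
  other_centric / slow : 500
n=500 prop_other=1.0000 mean_steps=41.94 sd_steps=1.05 nondecision=0
criterion: other-centric dominance: prop_other >= 0.95
verdict: pass
```

All 500 simulated decisions are other-centric and won by the slow
process, in about 42 steps on average: the strategy dominates even
though it accumulates at half the fast process's rate.  The same runs
are available from Python:

```python
from doublewell import preset, run_batch

results, summary = run_batch(preset("fig4"), n_trials=500, seed=1)
print(summary.prop_other)   # 1.0
print(summary.mean_steps)   # 41.94
```

The noise-free landscape behind any regime can be inspected directly —
for the symmetric uncoupled preset the nine equilibria of the map form
the 3 × 3 product of {−1, 0, +1} on each axis (4 stable wells, 4
saddles, 1 unstable origin):

```
$ doublewell fixedpoints --preset fig2
 x_fast  x_slow  eig_mag_1  eig_mag_2 classification
   -1.0    -1.0        0.6        0.6         stable
   -1.0     0.0        0.6        1.2         saddle
   ...
    1.0     1.0        0.6        0.6         stable
```

`doublewell simulate`, `batch`, `sweep` and `field` cover single
trajectories, seeded batches, parameter sweeps and vector-field export;
every command takes `--seed` and writes its full configuration into the
output file header, so runs are bitwise reproducible.

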