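# rxnloop

Closed-loop Bayesian optimization of reaction conditions, built for the
kind of problem carbohydrate protective-group chemistry poses: large
zero-yield regions, mixed continuous/ordinal/categorical condition spaces,
and strong substrate specificity. The package re-implements a
self-driving-lab optimizer — Gaussian-process surrogate, expected
improvement with a dual-xi exploration schedule, Latin-hypercube
initialization, PCA-descriptor ordinal encoding of chemical categoricals,
and transfer learning across substrates via a task variable — together with
a synthetic benzoylation-yield oracle that stands in for the synthesis
robot and chromatograph, so the whole loop runs and can be benchmarked on
one desk CPU.

Intended users: people building or studying autonomous reaction-optimization
loops, and anyone who wants a reproducible mixed-space BO testbed with a
chemically-shaped landscape.

## The method

The optimizer models the yield y(x) of a reaction under conditions x with a
GP over the normalized space (continuous → affine [0,1], ordinal → rank,
categorical → one-hot), kernel σ_f²·Matérn₅⁄₂(x, x′) + σ_n²δ, and proposes
the next experiment by maximizing expected improvement

    EI(x) = (μ(x) − f* − ξ)·Φ(z) + σ(x)·φ(z),   z = (μ(x) − f* − ξ)/σ(x)

with the dual schedule ξ = ξ_high (explore) for the first `changeover`
experiments and ξ = ξ_low (exploit) after. Discrete reagents get a
*meaningful* integer ordering beforehand: a correlation-matrix PCA of their
physicochemical descriptors, items ranked along PC1. Transfer learning adds
one categorical "sugar" variable: histories from related substrates enter
the training set with their own label while suggestions stay pinned to the
substrate being optimized.

The synthetic oracle models the consecutive acylation reactant → mono → di
with closed-form kinetics whose rates respond to every searched condition
(logistic base gate, solvent multipliers, log-normal concentration
response, reagent-equivalent saturation, and stoichiometric suppression of
the second acylation), plus Gaussian measurement noise (σ = 2 yield-points).
See `docs/methods.md` for the full model and design rationale.

## Worked example

Run a 24-experiment closed loop on the packaged 7-parameter space against
the glucoside-like simulator profile:

```
$ python -m rxnloop run --config cl1 --budget 24 --n-initial 8 \
      --changeover 16 --seed 7 --profile glucoside --out demo_run
history written to demo_run/history.csv
best observed mono yield: 93.6%
convergence (window 10, tol 1): 8
```

The loop spent 8 experiments on the Latin-hypercube design, explored with
ξ = 1.0 until experiment 16, then exploited with ξ = 0.01; the best
observed 6-O-monobenzoylation yield was 93.6% (the landscape's noise-free
maximum is ≈ 98%), and the incumbent stopped improving by more than
1 yield-point per 10 experiments after experiment 8 — this short a run
already sits in the optimum basin because seed 7's initial design contained
a rare non-zero-yield recipe. `demo_run/history.csv` holds one row per
experiment (conditions, species fractions, score, phase, seed);
`manifest.json` records the config digest and master seed, and re-running
the same command resumes or reproduces the run bit-identically.

The same machinery is available as a library:

```python
import rxnloop as rl

space   = rl.configs.load_space("cl1")
profile = rl.make_profiles()["glucoside"]
cfg = rl.LoopConfig(space=space, schedule=rl.XiSchedule(1.0, 0.01, 48, 12),
                    budget=70, objective="mono", profile=profile, master_seed=1)
history = rl.run_closed_loop(cfg)
print(rl.best_so_far(history)[-1])
```

Other subcommands: `rxnloop encode` (descriptor PCA → integer map),
`rxnloop bench` (the optimizer and transfer benchmarks), `rxnloop report`
(best-so-far trace and convergence diagnostics for a saved history).

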