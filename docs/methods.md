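# Methods

## The problem

Regioselective benzoylation of an unprotected glycoside — installing a
benzoyl group on the 6-OH (mono) or the 3- and 6-OH (di) of a sugar with
several free hydroxyls — has no obvious optimal conditions: yields are zero
over large parts of condition space and the optimum is substrate-specific.
`rxnloop` implements the closed-loop strategy for this problem: a Bayesian
optimizer proposes one experiment at a time over a mixed
continuous/ordinal/categorical condition space, an oracle (robot + UPLC in
the laboratory; a synthetic yield simulator here) measures it, and the
surrogate is updated. Transfer learning reuses optimization histories from
related substrates through a single extra categorical variable.

## The reaction space

Seven parameters are searched simultaneously: equivalents of benzoylating
reagent (continuous), equivalents of base (continuous), concentration in
mol/L (continuous), benzoylating reagent identity (ordinal integer, 1 =
BzCl, 2 = Bz2O), base identity (ordinal integer 1–9, ordered by descriptor
PCA), the delay t1 in minutes between base and reagent addition (ordinal
grid 0–20), and the solvent (categorical: 4 pure solvents and their six 1:1
mixtures). Reaction time (1 h) and ambient temperature are constants of the
workflow, not parameters.

The packaged first-loop space (`configs/cl1.yaml`) uses eq-Bz 1–4, eq-base
1–16.7 and conc 0.04–0.15 M. Only the 16.7 eq-base ceiling is anchored by
the study design; the remaining continuous ranges are package assumptions
chosen so that the space is demonstrably optimizable within a ~70-experiment
budget, matching the scale at which the original campaigns converged. The
follow-up space (`cl2`/`cl3`) fixes reagent and base to the first-loop
incumbents, raises eq-base to 30 and replaces the solvent categorical with a
continuous MeCN:THF mixing ratio. The transfer space widens the continuous
ranges (eq-Bz to 10, eq-base to 30, conc to 0.2 M) and appends the "sugar"
task categorical. The four pure solvents are MeCN, THF, dioxane and toluene;
the fourth is an assumption (only three are named in the published optima).

## Descriptor encoding of the bases

Nine bases are described by nine physicochemical descriptors (molecular
weight, density, refractive index, melting point, boiling point, logP,
dipole moment, polar TPSA, pKaH). Because units are incommensurate, columns
are standardized (zero mean, unit sample sd; constant columns dropped with a
warning) and PCA is run on the result — correlation-matrix PCA. Items are
ranked along PC1 and assigned consecutive integers 1..n; the sign of PC1 is
fixed by requiring a named reference item (triethylamine) to receive
integer 1. Ties are broken lexicographically. The shipped base descriptor
table (`data/bases_descriptors_reconstructed.csv`) is a reconstruction from
standard literature values, not the original table; tests assert only the
two published anchor facts on it (Et3N → 1, DIPEA → 2).

## Surrogate

A single-output GP over the normalized space: continuous parameters scaled
affinely to [0,1], ordinals by rank, categoricals one-hot encoded with
columns scaled by 1/sqrt(2) so any two levels sit at Euclidean distance 1.
Kernel: signal variance × anisotropic Matérn-5/2 + white noise, fitted by
maximizing the log marginal likelihood (L-BFGS, seeded multi-restart,
lengthscale bounds [1e-2, 20] on numeric coordinates). Outputs are
standardized to zero mean / unit variance (skipped when all observations
coincide). Jitter 1e-10 stabilizes the factorization; with the default 1e-8
the posterior std at a noise-free training point would exceed the package's
own interpolation contract.

Two kernel choices matter in practice and were made deliberately:

* **One-hot lengthscales are bounded to [0.5, 3].** Free ARD scales happily
  push a single level's column to the bound and thereby erase that level's
  evidence — in transfer runs this silently discarded everything the priors
  knew about one solvent. Bounded scales keep every level's data in play.
* **One-hot columns (including the task variable) start at lengthscale 2:**
  levels and tasks are presumed similar until the data identifies
  otherwise. A constant block (only one observed task) keeps this prior
  value, which is what makes prior-task records informative at all.

## Acquisition

Expected improvement with the dual-xi schedule: high xi while fewer than
`changeover` experiments have completed, low xi after (strict comparison;
the LHS block counts; by default prior records do not, exposed as a flag).
EI is evaluated on the standardized-output scale, so xi = 1.0 means one
standard deviation of observed yields — genuinely explorative — and 0.01 is
near-pure exploitation.

Two conventions depart from the most naive EI and together they decide
whether the loop works:

* **Latent-function std.** The predictive std fed to EI excludes the fitted
  white-noise term. With noise included, re-measuring a noisy incumbent has
  permanently positive EI and the loop crawls around one point.
* **Posterior-mean incumbent.** f* is the best *posterior mean* over
  evaluated current-task points, not the best noisy observation; a +2-sigma
  noise spike in the incumbent otherwise deflates EI everywhere and stalls
  the exploitative phase. Before any current-task observation exists (a
  transfer warm start), f* is the model's best prediction for the current
  task, so the first suggestions probe the prior task's optimum under the
  new substrate.

Suggestion maximizes EI by enumerating every free ordinal/categorical level
combination (a seeded subsample above 5000), evaluating several random
continuous settings per combination in one vectorized batch (with a minimum
sweep density so small spaces are covered), and polishing the best rows by
bounded Powell search over the continuous coordinates. Posterior std is
evaluated in two stages (mean-only prefilter) because it costs O(n²) per
point. An argmax within 1e-6 normalized distance of a previous experiment is
skipped for the next-best distinct optimum.

When the EI surface degenerates (no candidate promises more than 1e-3
standardized units of improvement during the high-xi phase, or 1e-8 during
low xi), the suggestion falls back to the exploration limit of EI: during
high xi it screens the *discrete* identity conditions the way a chemist
would — the level combination most uncertain/far from anything evaluated for
this substrate, held at the incumbent's continuous settings, so an untried
solvent is judged under otherwise-promising conditions rather than at a
random corner; during low xi it sits on the model's predicted optimum.

Hyperparameters are re-optimized every `refit_every = 3` experiments
(anchored to the record count, so a resumed loop recomputes identical
values); between anchors the previous optimum is reused at the new data.

## Transfer learning

The space gains a categorical "sugar" parameter listing the substrates.
Suggestions are pinned to the substrate being optimized; historical records
enter the training set with their own label. The incumbent for EI is
computed over current-task records only; the prior records' best is the
"old max" baseline. Records that do not fit the child space are dropped
with per-record reasons, never clipped; a categorical solvent maps to a
MeCN:THF ratio where derivable (MeCN → 0, THF → 1, 1:1 → 0.5). In the
benchmark harness warm starts count the prior records against the xi
changeover — the loop exploits from the first suggestion, matching how the
warm campaigns behaved — while cold starts use the standard schedule.

## The yield simulator

The oracle models the consecutive acylation A → B → C (reactant →
6-O-mono → 3,6-di) with closed-form pseudo-first-order kinetics over the
fixed 1 h. Both rates are products of condition responses: a logistic gate
in the PCA-ordered base integer (strong amines at low integers work, weak
pyridines give the large zero-yield regions), a saturating response in base
equivalents, per-solvent multipliers (mixtures: geometric mean plus a small
mixture bonus), a log-normal concentration response, a saturating response
in reagent equivalents for the first acylation and a logistic *suppression*
of the second below ~3–4 equivalents — the stoichiometric reason excess
reagent drives the di product. The second acylation's solvent dependence is
deliberately weaker (multiplier^0.3): otherwise, at full conversion, the
weakest converting solvent would minimize the di leak and win, inverting
every solvent preference at the top of the landscape. A smooth seeded
random-Fourier "texture" field over the non-eq-Bz conditions (clipped at
±1 sd) adds substrate idiosyncrasies without breaking the built-in
monotonicity of conversion in reagent equivalents. Measurement noise is
Gaussian with sigma = 2 yield-points (chromatographic repeatability scale;
no replicate statistics were published), clipped to [0, 100].

Three profiles (glucoside-, thiomannoside-, galactoside-like) share the
qualitative optimum family — strong amine base, anhydride, reagent excess,
THF-leaning solvents — and differ in concentration optima, solvent
tolerances, t1 preference, and substrate-specific "catalytic" bases
(additive bumps on the activation of mid-integer bases). The constants were
chosen once so that the design targets hold simultaneously: under a
12-point Latin hypercube on the first-loop space the expected number of
>5% yields is ≤ 2 (a sparse-success landscape); the pairwise Spearman
correlation of yields over 1000 random conditions lies in 0.3–0.8 (related
enough for transfer, distinct optima); the di optimum needs more reagent
than the mono optimum for every substrate; and each landscape is
optimizable to ≥95% of its recorded maximum within a ~70-experiment budget,
as the real campaigns were. Each profile's noise-free maxima (dense random
search with local polish, 1e5 candidates) are recorded on the profile for
benchmarking.

What the simulator does **not** model: UPLC response-factor differences
(scoring assumes equal response factors over the three tracked species),
acyl migration, HCl side reactions, scale and equipment effects — exactly
the factors the original study identified as the robot-to-bench gap.
Passing benchmarks on the simulator therefore demonstrates the optimizer's
behavior on a landscape with the *statistical* signature of the real
problem, not any chemical claim.

## Benchmarks and problem sizes

The cold-start benchmark runs 20 seeded loops of budget 70 (12 LHS,
changeover 48, xi 1.0 → 0.01) on the glucoside profile plus equal-budget
random search. The transfer benchmark builds one fixed 71-record glucoside
campaign, then runs 20 cold loops (budget 60) and 20 warm loops (budget 40,
changeover 24, xi 1.0 → 0.02) on the thiomannoside profile, plus 20 warm
loops with a third (galactoside) history stacked on top for the saturation
probe. Convergence reporting uses a window of 10 experiments and a
tolerance of 1 yield-point — a diagnostic, never a stopping rule; the
budget is the stopping rule. `scripts/acceptance.py` re-runs the same
computations at 10 seeds per arm.

## Known limitations

* The surrogate treats ordinals as continuous ranks; a grid with strongly
  non-metric levels would be mis-modelled.
* Acquisition optimization is approximate (enumeration × multi-start local
  search); the dense-grid test bounds the gap only in low dimension.
* The exploration fallback is a heuristic beyond textbook EI; it is
  documented behavior, controlled by two thresholds
  (`HIGH_XI_EI_MIN = 1e-3`, `EI_FLOOR = 1e-8` standardized units).
* Transfer rests entirely on the task-categorical trick; no multi-task
  kernels are attempted, by design.
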