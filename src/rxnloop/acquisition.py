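"""Expected improvement with a dual-xi exploration schedule.

The acquisition function is classic expected improvement

    EI(x) = (mu - f* - xi) * Phi(z) + sigma * phi(z),   z = (mu - f* - xi) / sigma

where ``f*`` is the incumbent (best observed yield so far) and ``xi`` the
exploration margin.  Instead of committing to one xi, the loop follows the
dual schedule: a *high* xi while fewer than ``changeover`` experiments have
completed (broad traversal of the surface), then a *low* xi (careful
refinement around the located optimum).  The initial design, before any
model exists, is a seeded Latin hypercube over the free dimensions.

EI is evaluated on the surrogate's standardized-output scale, so xi = 1.0
means "one standard deviation of the observed yields" — explorative — and
xi = 0.01 is nearly pure exploitation.

Suggestion over the mixed space enumerates every free ordinal/categorical
level combination (sampling a seeded subset if there are more than
``MAX_COMBOS``), evaluates EI at several random continuous settings per
combination in one vectorized batch, then polishes the best few by
derivative-free local search over the continuous coordinates.  An argmax
that coincides with an already-run experiment (within ``DUP_TOL`` normalized
distance) is skipped in favour of the next-best distinct optimum: a robot
should not repeat an identical experiment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import norm, qmc

from .gp import GPModel
from .space import Candidate, ReactionSpace, SpaceError

logger = logging.getLogger("rxnloop")

MAX_COMBOS = 5000
DUP_TOL = 1e-6
EI_FLOOR = 1e-8  # low-xi: EI below this is numerical noise
HIGH_XI_EI_MIN = 1e-3  # high-xi: minimum EI worth exploiting over exploring
N_STARTS = 3  # continuous starts per discrete combination (incl. seeded)
N_REFINE = 6  # top-EI rows polished by local search
REFINE_MAXFEV = 60


@dataclass(frozen=True)
class XiSchedule:
    """Dual-xi schedule: high xi before ``changeover`` completed experiments,
    low xi after; ``n_initial`` Latin-hypercube points open the loop."""

    high_xi: float
    low_xi: float
    changeover: int
    n_initial: int

    def __post_init__(self):
        if not (self.high_xi >= self.low_xi > 0):
            raise ValueError("need high_xi >= low_xi > 0")
        if not (self.changeover >= self.n_initial >= 0):
            raise ValueError("need changeover >= n_initial >= 0")


def current_xi(schedule: XiSchedule, n_completed: int) -> float:
    """xi in force after ``n_completed`` experiments (LHS block included);
    the comparison is strict: high xi while n_completed < changeover."""
    if n_completed < 0:
        raise ValueError("n_completed must be >= 0")
    return schedule.high_xi if n_completed < schedule.changeover else schedule.low_xi


def expected_improvement(mean, std, f_best: float, xi: float):
    """Closed-form EI; vectorized; std = 0 handled by its limit
    max(mean - f_best - xi, 0)."""
    mean = np.asarray(mean, dtype=float)
    std = np.asarray(std, dtype=float)
    if np.any(std < 0):
        raise ValueError("std must be >= 0")
    imp = mean - f_best - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, imp / np.where(std > 0, std, 1.0), 0.0)
    ei = np.where(
        std > 0,
        imp * norm.cdf(z) + std * norm.pdf(z),
        np.maximum(imp, 0.0),
    )
    out = np.maximum(ei, 0.0)
    return float(out) if out.ndim == 0 else out


# ----- initial design -------------------------------------------------------


def latin_hypercube(n: int, space: ReactionSpace, seed: int) -> list[Candidate]:
    """Seeded Latin-hypercube design of ``n`` valid candidates.

    Each free continuous/ordinal dimension receives exactly one point per
    equal-probability stratum [k/n, (k+1)/n); each free categorical cycles
    its levels (logged when n < #levels) and is shuffled independently.
    Pinned and fixed parameters hold their values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    numeric = [
        p
        for p in space.free_params
        if p.kind in ("continuous", "ordinal") and p.name not in space.pinned
    ]
    cats = [
        p
        for p in space.free_params
        if p.kind == "categorical" and p.name not in space.pinned
    ]
    if numeric:
        sampler = qmc.LatinHypercube(d=len(numeric), seed=rng)
        U = sampler.random(n)
    else:
        U = np.zeros((n, 0))
    cat_draws: dict[str, list] = {}
    for p in cats:
        L = len(p.levels)
        if n < L:
            logger.info(
                "LHS n=%d < %d levels of %r: a random subset of levels is used",
                n,
                L,
                p.name,
            )
        reps = int(np.ceil(n / L))
        tiled = list(p.levels) * reps
        rng.shuffle(tiled)
        cat_draws[p.name] = tiled[:n]
    out = []
    for i in range(n):
        values = {}
        for p in space.params:
            if p.name in space.pinned:
                values[p.name] = space.pinned[p.name]
            elif p.is_fixed:
                values[p.name] = p.fixed_value
            elif p in numeric:
                u = U[i, numeric.index(p)]
                if p.kind == "continuous":
                    values[p.name] = p.lower + u * (p.upper - p.lower)
                else:
                    values[p.name] = p.levels[min(int(u * len(p.levels)), len(p.levels) - 1)]
            else:
                values[p.name] = cat_draws[p.name][i]
        c = Candidate(values)
        space.validate(c)
        out.append(c)
    return out


# ----- suggestion over the mixed space -------------------------------------


def _discrete_combos(space: ReactionSpace, rng: np.random.Generator):
    """All (or a seeded subset of) free ordinal/categorical level settings."""
    discrete = [
        p for p in space.free_params if p.kind in ("ordinal", "categorical")
    ]
    per_param = []
    for p in discrete:
        if p.name in space.pinned:
            per_param.append([space.pinned[p.name]])
        else:
            per_param.append(list(p.levels))
    total = int(np.prod([len(v) for v in per_param])) if per_param else 1
    if total <= MAX_COMBOS:
        combos = list(itertools.product(*per_param))
    else:
        logger.info("sampling %d of %d discrete combinations", MAX_COMBOS, total)
        combos = [
            tuple(v[rng.integers(len(v))] for v in per_param)
            for _ in range(MAX_COMBOS)
        ]
    return [p.name for p in discrete], combos


def _history_arrays(history, space: ReactionSpace):
    X = space.normalize_many([r.candidate for r in history])
    return X


def incumbent(history, task: object | None = None) -> float:
    """Best observed yield.  With a task label, current-task records are
    preferred; the prior records' "old max" is the fallback before any
    current-task result exists."""
    current = [
        r.score
        for r in history
        if r.score is not None and getattr(r, "phase", None) != "prior"
    ]
    if current:
        return float(max(current))
    prior = [r.score for r in history if r.score is not None]
    if not prior:
        raise ValueError("history has no scored records")
    return float(max(prior))


def suggest(
    model: GPModel,
    space: ReactionSpace,
    schedule: XiSchedule,
    history,
    seed: int,
    n_starts: int = N_STARTS,
    n_refine: int = N_REFINE,
    n_completed: int | None = None,
) -> Candidate:
    """Return the (approximate) EI-argmax candidate for the next experiment.

    ``history`` is the list of completed experiment records; it sets the
    incumbent (the best posterior mean over evaluated current-task
    conditions — noise-aware), the xi currently in force (completed
    non-prior experiments counted against the schedule's changeover, unless
    ``n_completed`` overrides the tally) and the duplicate-suppression set.
    Deterministic under ``seed``.
    """
    if not history:
        raise ValueError("history must be non-empty (run the initial design first)")
    free = space.free_params
    if not free:
        raise SpaceError("no free parameters to suggest over")
    rng = np.random.default_rng(seed)
    if n_completed is None:
        n_completed = sum(1 for r in history if getattr(r, "phase", None) != "prior")
    xi = current_xi(schedule, n_completed)

    names, combos = _discrete_combos(space, rng)
    cont = [
        p
        for p in free
        if p.kind == "continuous" and p.name not in space.pinned
    ]
    n_cont_starts = max(1, n_starts) if cont else 1
    if cont:
        # small discrete grids get proportionally more continuous starts, so
        # the sweep never misses a narrow EI peak for lack of density
        n_cont_starts = max(n_cont_starts, int(np.ceil(512 / len(combos))))

    # one vectorized EI sweep over combos × continuous starts, assembled
    # directly in normalized coordinates (no per-row Candidate objects)
    hist_X = _history_arrays(history, space)
    scores = np.array(
        [r.score if r.score is not None else -np.inf for r in history]
    )
    best_prev = history[int(np.argmax(scores))]
    layout: dict[str, slice] = {}
    i = 0
    for p in free:
        w = len(p.levels) if p.kind == "categorical" else 1
        layout[p.name] = slice(i, i + w)
        i += w
    templates = np.zeros((len(combos), space.dim))
    for name, vals in zip(names, zip(*combos) if combos and names else []):
        p = space[name]
        sl = layout[name]
        if p.kind == "ordinal":
            L = len(p.levels)
            idx = np.array([p.levels.index(v) for v in vals], dtype=float)
            templates[:, sl.start] = idx / (L - 1) if L > 1 else 0.0
        else:
            for row, v in enumerate(vals):
                templates[row, sl.start + p.levels.index(v)] = 1.0
    X_all = np.repeat(templates, n_cont_starts, axis=0)
    best_x = space.normalize(best_prev.candidate)
    for p in cont:
        col = layout[p.name].start
        u = rng.uniform(size=X_all.shape[0])
        u[::n_cont_starts] = best_x[col]  # one start at the incumbent
        X_all[:, col] = u
    # two-stage evaluation: posterior std costs O(n^2) per point, so it is
    # computed only for the most promising rows (by posterior mean) plus a
    # random subset for uncertainty coverage
    X = X_all
    if X_all.shape[0] > 2500:
        mu_all = model.standardized_mean(X_all)
        keep = np.argpartition(mu_all, -1500)[-1500:]
        rest = np.setdiff1d(np.arange(X_all.shape[0]), keep)
        keep = np.concatenate(
            [keep, rng.choice(rest, size=min(1000, rest.size), replace=False)]
        )
        X = X_all[keep]
    mu, sd = model.standardized_predict(X)
    cur_scored = [
        r
        for r in history
        if r.score is not None and getattr(r, "phase", None) != "prior"
    ]
    if cur_scored:
        # noise-aware incumbent: the best *posterior mean* over evaluated
        # current-task conditions.  The best observed yield is inflated by
        # favourable measurement noise; using it with a latent-function std
        # makes EI needlessly pessimistic everywhere.
        mu_obs = model.standardized_mean(
            space.normalize_many([r.candidate for r in cur_scored])
        )
        f_best = float(mu_obs.max())
    else:
        # warm start before any current-task result: the incumbent is what
        # the surrogate believes this substrate can reach, so the first
        # suggestions probe the prior tasks' optima under the new task
        f_best = float(mu.max())
    ei = expected_improvement(mu, sd, f_best, xi)

    # EI -> 0 exploration limit.  In the high-xi regime the schedule's
    # intent is broad traversal: once no candidate promises a material
    # expected improvement (the incumbent towers over the posterior mean and
    # the EI surface collapses onto a ring of incumbent perturbations), pure
    # EI degenerates.  The fallback then screens the *discrete* identity
    # conditions (solvent, base, reagent, delay) the way a chemist would:
    # pick the level combination farthest from anything evaluated for this
    # substrate, holding the continuous settings at the incumbent's — so an
    # untried solvent is judged under otherwise-promising conditions, not at
    # a random corner.  In the low-xi (exploitative) regime even tiny EI is
    # pursued; only a numerically degenerate surface triggers the fallback.
    ei_min = HIGH_XI_EI_MIN if xi == schedule.high_xi and (
        schedule.high_xi > schedule.low_xi
    ) and n_completed < schedule.changeover else EI_FLOOR
    degenerate = bool(ei.max() < ei_min)
    explore = degenerate and ei_min == HIGH_XI_EI_MIN
    if explore:
        # rank the discrete identity settings by posterior uncertainty at the
        # incumbent's continuous coordinates, then break ties toward
        # conditions far (in the discrete coordinates) from anything already
        # run for this substrate
        cur = [r for r in history if getattr(r, "phase", None) != "prior"]
        ref = space.normalize_many([r.candidate for r in (cur or history)])
        X = X_all[:: n_cont_starts]  # incumbent-continuous row per combo
        _, sd_inc = model.standardized_predict(X)
        disc = ~space.continuous_mask
        dist = (
            cdist(X[:, disc], ref[:, disc]).min(axis=1)
            if disc.any()
            else cdist(X, ref).min(axis=1)
        )
        score = sd_inc + 1e-3 * dist
    elif degenerate:
        # exploitative endgame: EI says nothing beats the incumbent, so sit
        # on the model's predicted optimum (distinct points on the plateau)
        score = mu
    else:
        score = ei

    order = np.argsort(score)[::-1]
    cont_idx = np.where(space.continuous_mask)[0]

    def neg_ei(xc, x_full):
        x = x_full.copy()
        x[cont_idx] = np.clip(xc, 0.0, 1.0)
        m, s = model.standardized_predict(x[None, :])
        if degenerate:
            return -float(m[0])
        return -float(expected_improvement(m, s, f_best, xi)[0])

    candidates: list[tuple[float, np.ndarray]] = []
    top = order[: max(n_refine, 1)]
    for idx in top:
        x0 = X[idx].copy()
        if len(cont_idx) > 0 and not explore:
            res = minimize(
                neg_ei,
                x0[cont_idx],
                args=(x0,),
                method="Powell",
                bounds=[(0.0, 1.0)] * len(cont_idx),
                options={"maxfev": REFINE_MAXFEV, "xtol": 1e-3, "ftol": 1e-4},
            )
            x = x0.copy()
            x[cont_idx] = np.clip(res.x, 0.0, 1.0)
            candidates.append((-res.fun, x))
        else:
            candidates.append((float(score[idx]), x0))
    # also keep the unrefined sweep, in rank order, as fallbacks
    for idx in order[: 5 * max(n_refine, 1)]:
        candidates.append((float(score[idx]), X[idx]))
    candidates.sort(key=lambda t: -t[0])

    for _, x in candidates:
        cand = space.denormalize(x)
        xn = space.normalize(cand)  # snapped coordinates
        d = np.linalg.norm(hist_X - xn[None, :], axis=1)
        if np.min(d) > DUP_TOL:
            space.validate(cand, enforce_pinned=True)
            return cand
    # everything duplicated (tiny spaces): perturb randomly until distinct
    for _ in range(200):
        cand = space.sample(rng)
        xn = space.normalize(cand)
        if np.min(np.linalg.norm(hist_X - xn[None, :], axis=1)) > DUP_TOL:
            return cand
    logger.warning("could not find a non-duplicate suggestion; returning argmax")
    return space.denormalize(candidates[0][1])
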