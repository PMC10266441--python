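"""Closed-loop orchestration: LHS phase → BO (high xi) → BO (low xi).

``run_closed_loop`` drives the propose → execute → measure → update cycle
against an oracle (the built-in yield simulator, or any callable standing in
for a robot + chromatograph), persisting the history to a plain tabular file
after every experiment so a crashed loop resumes bit-identically under the
same master seed.

Scoring follows the normalized-peak-area convention over the three tracked
species (reactant, mono-, di-benzoylated), assuming equal chromatographic
response factors — a declared simplification, as no per-species calibration
is modelled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import acquisition, gp
from .acquisition import XiSchedule, current_xi, latin_hypercube
from .simulator import SubstrateProfile, measure, species_fractions
from .space import Candidate, ReactionSpace, candidate_from_row

logger = logging.getLogger("rxnloop")

PHASES = ("prior", "lhs", "bo_high", "bo_low")
SPECIES = ("reactant", "mono", "di")


@dataclass
class ExperimentRecord:
    """One proposed-and-measured experiment."""

    index: int
    candidate: Candidate
    fractions: tuple[float, float, float] | None  # pre-noise species fractions
    score: float | None  # yield-percent; None for failed experiments
    phase: str
    task: str | None = None
    seed: int | None = None
    timestamp: str | None = None  # informational only; never persisted to history

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.score is not None and not (0.0 <= self.score <= 100.0):
            raise ValueError("score must be in [0, 100]")


@dataclass
class LoopConfig:
    """Everything one closed loop needs.

    ``oracle`` may replace ``profile``: a callable
    ``(candidate, rng) -> (fractions, score)`` supplying an external results
    channel.  ``budget`` counts *new* experiments (priors excluded).
    """

    space: ReactionSpace
    schedule: XiSchedule
    budget: int
    objective: str = "mono"
    profile: SubstrateProfile | None = None
    oracle: Callable | None = None
    priors: Sequence[ExperimentRecord] = field(default_factory=tuple)
    master_seed: int = 0
    task: str | None = None
    out_dir: str | Path | None = None
    count_prior_in_tally: bool = False
    gp_restarts: int = 2
    refit_every: int = 3  # full hyperparameter re-optimization cadence
    max_retries: int = 0

    def __post_init__(self):
        if self.objective not in ("mono", "di"):
            raise ValueError("objective must be 'mono' or 'di'")
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if not self.priors and self.budget < self.schedule.n_initial:
            raise ValueError("budget must cover the initial design")
        if self.profile is None and self.oracle is None and self.budget > 0:
            raise ValueError("need a simulator profile or an oracle")


def _derive_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def score_from_areas(areas: Mapping[str, float], objective: str) -> float:
    """Yield-percent from chromatogram peak areas: 100 × area(objective) /
    Σ(areas of the three tracked species), i.e. equal response factors."""
    if objective not in ("mono", "di"):
        raise ValueError("objective must be 'mono' or 'di'")
    vals = {s: float(areas[s]) for s in SPECIES}
    if any(v < 0 for v in vals.values()):
        raise ValueError("areas must be non-negative")
    total = sum(vals.values())
    if total == 0:
        raise ValueError("all species areas are zero")
    return 100.0 * vals[objective] / total


# ----- persistence ----------------------------------------------------------


def history_to_frame(history: Sequence[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for r in history:
        row = {"index": r.index, "phase": r.phase, "task": r.task, "seed": r.seed}
        row.update(r.candidate.values)
        if r.fractions is not None:
            for s, f in zip(SPECIES, r.fractions):
                row[f"frac_{s}"] = f
        row["score"] = r.score
        rows.append(row)
    return pd.DataFrame(rows)


def save_history(history: Sequence[ExperimentRecord], path: str | Path) -> None:
    # default float formatting is shortest-roundtrip: a resumed loop must
    # refit on bit-identical inputs
    history_to_frame(history).to_csv(path, index=False)


def load_history(path: str | Path, space: ReactionSpace) -> list[ExperimentRecord]:
    # round_trip parsing: a resumed loop must see bit-identical floats
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        fractions = None
        if "frac_reactant" in row and not pd.isna(row["frac_reactant"]):
            fractions = tuple(float(row[f"frac_{s}"]) for s in SPECIES)
        records.append(
            ExperimentRecord(
                index=int(row["index"]),
                candidate=candidate_from_row(row, space),
                fractions=fractions,
                score=None if pd.isna(row["score"]) else float(row["score"]),
                phase=str(row["phase"]),
                task=None if pd.isna(row.get("task", np.nan)) else str(row["task"]),
                seed=None if pd.isna(row.get("seed", np.nan)) else int(row["seed"]),
            )
        )
    return records


def _config_digest(config: LoopConfig) -> str:
    payload = {
        "space": [
            (p.name, p.kind, p.lower, p.upper, p.levels, repr(p.fixed_value))
            for p in config.space.params
        ],
        "pinned": sorted(config.space.pinned.items()),
        "schedule": (
            config.schedule.high_xi,
            config.schedule.low_xi,
            config.schedule.changeover,
            config.schedule.n_initial,
        ),
        "budget": config.budget,
        "objective": config.objective,
        "profile": config.profile.name if config.profile else None,
        "master_seed": config.master_seed,
        "n_priors": len(config.priors),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


# ----- the loop -------------------------------------------------------------


def _evaluate(config: LoopConfig, candidate: Candidate, index: int, phase: str):
    seed = _derive_seed(config.master_seed, index, 0)
    rng = np.random.default_rng(seed)
    attempts = config.max_retries + 1
    for attempt in range(attempts):
        try:
            if config.oracle is not None:
                fractions, score = config.oracle(candidate, rng)
            else:
                fractions = species_fractions(candidate, config.profile)
                score = measure(
                    fractions, config.objective, config.profile.sigma_meas, rng
                )
            return ExperimentRecord(
                index=index,
                candidate=candidate,
                fractions=fractions,
                score=score,
                phase=phase,
                task=config.task,
                seed=seed,
            )
        except Exception as exc:  # oracle failure: record and continue
            logger.warning("experiment %d failed (attempt %d): %s", index, attempt, exc)
    return ExperimentRecord(
        index=index,
        candidate=candidate,
        fractions=None,
        score=None,
        phase=phase,
        task=config.task,
        seed=seed,
    )


def run_closed_loop(config: LoopConfig) -> list[ExperimentRecord]:
    """Run (or resume) one closed loop; returns priors + new records.

    The first ``schedule.n_initial`` experiments come from a seeded Latin
    hypercube — skipped entirely when prior records are supplied, which is
    the transfer-learning warm start.  Every further experiment is the EI
    argmax under the xi currently in force.  The history file is rewritten
    after each experiment; rerunning with the same ``out_dir`` and master
    seed resumes and reproduces the remainder bit-identically.
    """
    space = config.space
    history: list[ExperimentRecord] = list(config.priors)
    current: list[ExperimentRecord] = []

    out_path = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "history.csv"
        manifest = {
            "config_sha256": _config_digest(config),
            "master_seed": config.master_seed,
            "budget": config.budget,
            "objective": config.objective,
            "n_priors": len(config.priors),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if out_path.exists():
            current = [
                r for r in load_history(out_path, space) if r.phase != "prior"
            ]
            logger.info("resuming from %d completed experiments", len(current))
    history.extend(current)

    def flush():
        if out_path is not None:
            save_history(history, out_path)

    # --- initial design (cold start only) ---
    if not config.priors:
        design = latin_hypercube(
            config.schedule.n_initial, space, _derive_seed(config.master_seed, 0, 2)
        )
        while len(current) < min(config.schedule.n_initial, config.budget):
            i = len(current)
            rec = _evaluate(config, design[i], index=i + 1, phase="lhs")
            current.append(rec)
            history.append(rec)
            flush()

    # --- Bayesian optimization phase ---
    # Hyperparameters are re-optimized on a fixed cadence (every
    # ``refit_every`` experiments); in between, the most recent optimized
    # theta is reused at the new data.  The cadence depends only on the
    # record count, so a resumed loop recomputes the same thetas.
    fit_seed = _derive_seed(config.master_seed, 0, 3)
    theta_cache: dict[int, np.ndarray] = {}

    def optimized_theta(m: int) -> np.ndarray:
        if m not in theta_cache:
            prefix = list(config.priors) + current[:m]
            scored = [r for r in prefix if r.score is not None]
            sub = gp.fit(
                space.normalize_many([r.candidate for r in scored]),
                np.array([r.score for r in scored]),
                seed=fit_seed,
                cat_mask=space.onehot_mask,
                n_restarts=config.gp_restarts,
            )
            theta_cache[m] = sub.theta
        return theta_cache[m]

    while len(current) < config.budget:
        index = len(current) + 1
        tally = len(current) + (
            len(config.priors) if config.count_prior_in_tally else 0
        )
        xi = current_xi(config.schedule, tally)
        phase = "bo_high" if xi == config.schedule.high_xi and (
            tally < config.schedule.changeover
        ) else "bo_low"
        scored = [r for r in history if r.score is not None]
        if not scored:
            raise RuntimeError(
                "no successfully scored experiments to fit the surrogate on"
            )
        X = space.normalize_many([r.candidate for r in scored])
        y = np.array([r.score for r in scored])
        m_anchor = config.refit_every * (len(current) // config.refit_every)
        model = gp.fit(
            X,
            y,
            seed=fit_seed,
            cat_mask=space.onehot_mask,
            theta=optimized_theta(m_anchor),
            optimize=False,
        )
        cand = acquisition.suggest(
            model,
            space,
            config.schedule,
            scored,
            seed=_derive_seed(config.master_seed, index, 1),
            n_completed=tally,
        )
        rec = _evaluate(config, cand, index=index, phase=phase)
        current.append(rec)
        history.append(rec)
        flush()
    return history


# ----- diagnostics ----------------------------------------------------------


def best_so_far(history: Sequence[ExperimentRecord]) -> np.ndarray:
    """Running incumbent yield over the current (non-prior) records; failed
    experiments carry the previous incumbent forward."""
    if not history:
        raise ValueError("history is empty")
    trace = []
    cur = 0.0
    for r in history:
        if r.phase == "prior":
            continue
        if r.score is not None:
            cur = max(cur, r.score)
        trace.append(cur)
    return np.asarray(trace)


def old_max(history: Sequence[ExperimentRecord]) -> float | None:
    """Highest observed yield among the prior records (the transfer
    baseline), or None without priors."""
    prior = [r.score for r in history if r.phase == "prior" and r.score is not None]
    return max(prior) if prior else None


def detect_convergence(
    history_or_trace, window: int = 10, tol: float = 1.0
) -> int | None:
    """Smallest experiment number i whose incumbent improves by < ``tol``
    yield-points over the next ``window`` experiments; None if never.

    A reporting diagnostic only — the stopping rule of a loop is its budget.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    trace = (
        np.asarray(history_or_trace, dtype=float)
        if isinstance(history_or_trace, (list, tuple, np.ndarray))
        and not (
            len(history_or_trace) > 0
            and isinstance(history_or_trace[0], ExperimentRecord)
        )
        else best_so_far(history_or_trace)
    )
    n = len(trace)
    for i in range(1, n - window + 1):  # 1-based experiment numbers
        if trace[i - 1 + window] - trace[i - 1] < tol:
            return i
    return None


def experiments_to_threshold(
    history: Sequence[ExperimentRecord], threshold: float
) -> int | None:
    """Number of current-task experiments until the incumbent first reaches
    ``threshold`` yield-percent; None if the budget never got there."""
    trace = best_so_far(history)
    hits = np.nonzero(trace >= threshold)[0]
    return int(hits[0]) + 1 if hits.size else None
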