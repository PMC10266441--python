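"""Transfer learning across substrates via a task categorical.

Optimization histories from related substrates ("sugars") are reused by
augmenting the reaction space with one extra categorical parameter carrying
the substrate identity.  Prior records enter the surrogate's training set
with their own task level; suggestions are pinned to the substrate currently
being optimized.  No change to the optimizer itself is needed — the task
variable alone lets the GP share structure between substrates while keeping
their optima distinct.

The incumbent used by expected improvement is computed over current-task
records only (the prior records' best is merely the "old max" baseline), and
prior records do not count against the xi changeover by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .loop import ExperimentRecord
from .space import Candidate, ParameterSpec, ReactionSpace, SpaceError

logger = logging.getLogger("rxnloop")

TASK_PARAM = "sugar"

# categorical solvent -> MeCN:THF mixing ratio, where derivable
SOLVENT_TO_RATIO = {"MeCN": 0.0, "THF": 1.0, "MeCN/THF": 0.5}


@dataclass
class TaskLibrary:
    """Per-task prior histories (flat tables: condition columns + a
    mandatory task column + score)."""

    histories: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.histories = dict(self.histories)
        if len(set(self.histories)) != len(self.histories):
            raise SpaceError("duplicate task labels")

    @property
    def tasks(self) -> list[str]:
        return list(self.histories)

    def add_records(self, task: str, records: Sequence[ExperimentRecord]) -> None:
        from .loop import history_to_frame

        df = history_to_frame([r for r in records if r.score is not None])
        df[TASK_PARAM] = task
        self.histories[task] = df


def augment_with_task(
    space: ReactionSpace, tasks: Sequence[str], current: str
) -> ReactionSpace:
    """Append (or re-pin) the task categorical; suggestions are constrained
    to ``current`` while historical records may carry any task level."""
    tasks = list(tasks)
    if current not in tasks:
        raise SpaceError(f"current task {current!r} not among tasks {tasks}")
    pinned = dict(space.pinned)
    if TASK_PARAM in space:
        existing = space[TASK_PARAM]
        missing = [t for t in tasks if t not in existing.levels]
        if missing:
            raise SpaceError(f"space's task levels lack {missing}")
        params = space.params
    elif len(tasks) == 1:
        # degenerate augmentation: a single-task categorical is constant, so
        # freeze it outright (surrogate unchanged)
        params = space.params + (
            ParameterSpec(TASK_PARAM, "categorical", levels=tasks, fixed_value=current),
        )
        return ReactionSpace(params=params, metadata=dict(space.metadata), pinned=pinned)
    else:
        params = space.params + (
            ParameterSpec(TASK_PARAM, "categorical", levels=tasks),
        )
    pinned[TASK_PARAM] = current
    return ReactionSpace(params=params, metadata=dict(space.metadata), pinned=pinned)


def map_candidate_values(
    row: Mapping[str, object], space: ReactionSpace
) -> dict[str, object]:
    """Map a parent-space record's values into ``space``, deriving values
    for parameters the parent lacked where possible (categorical solvent →
    MeCN:THF ratio); raises :class:`SpaceError` when underivable."""
    values: dict[str, object] = {}
    for p in space.params:
        if p.name in row and not pd.isna(row[p.name]):
            raw = row[p.name]
            if p.kind == "continuous":
                values[p.name] = float(raw)
            elif p.kind == "ordinal":
                values[p.name] = int(float(raw))
            else:
                values[p.name] = str(raw)
        elif p.name == "solvent_ratio" and "solvent" in row:
            solvent = str(row["solvent"])
            if solvent not in SOLVENT_TO_RATIO:
                raise SpaceError(f"solvent {solvent!r} has no derivable ratio")
            values[p.name] = SOLVENT_TO_RATIO[solvent]
        elif p.is_fixed:
            values[p.name] = p.fixed_value
        else:
            raise SpaceError(f"record lacks parameter {p.name!r}")
    return values


def ingest_prior(
    library: TaskLibrary, space: ReactionSpace
) -> tuple[list[ExperimentRecord], dict]:
    """Validate prior histories into ``space`` as phase-"prior" records.

    Records that cannot be mapped or fall outside the space are dropped —
    never clipped — with per-record reasons in the returned report.
    """
    records: list[ExperimentRecord] = []
    report = {"kept": 0, "dropped": 0, "reasons": []}
    index = 0
    for task, df in library.histories.items():
        for _, row in df.iterrows():
            row = {library.column_map.get(k, k): v for k, v in row.items()}
            row.setdefault(TASK_PARAM, task)
            try:
                values = map_candidate_values(row, space)
                cand = Candidate(values)
                space.validate(cand)
                score = float(row["score"])
                if not 0.0 <= score <= 100.0:
                    raise SpaceError(f"score {score} outside [0, 100]")
            except (SpaceError, KeyError, TypeError, ValueError) as exc:
                report["dropped"] += 1
                report["reasons"].append(f"{task}[{index}]: {exc}")
                index += 1
                continue
            index += 1
            fractions = None
            if "frac_reactant" in row and not pd.isna(row["frac_reactant"]):
                fractions = (
                    float(row["frac_reactant"]),
                    float(row["frac_mono"]),
                    float(row["frac_di"]),
                )
            records.append(
                ExperimentRecord(
                    index=-len(records) - 1,  # priors sit before experiment 1
                    candidate=cand,
                    fractions=fractions,
                    score=score,
                    phase="prior",
                    task=task,
                )
            )
            report["kept"] += 1
    logger.info(
        "prior ingestion: kept %d, dropped %d", report["kept"], report["dropped"]
    )
    return records, report


def records_with_task(
    records: Sequence[ExperimentRecord], space: ReactionSpace, task: str
) -> list[ExperimentRecord]:
    """Tag plain-space records with a task level so they validate in the
    augmented ``space`` (used when recycling a cold-start history as priors)."""
    out = []
    for r in records:
        values = dict(r.candidate.values)
        values[TASK_PARAM] = task
        cand = Candidate(map_candidate_values(values, space))
        space.validate(cand)
        out.append(replace(r, candidate=cand, phase="prior", task=task))
    return out
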