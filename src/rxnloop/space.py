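"""Mixed reaction-condition search spaces.

A reaction space is an ordered collection of parameters of three kinds:

* **continuous** — physical quantities with finite bounds (equivalents of
  benzoylating reagent, equivalents of base, concentration in mol/L, a
  solvent mixing ratio, ...);
* **ordinal** — labelled integers with a meaningful 1-D ordering (the
  benzoylating reagent 1/2, the PCA-ordered base integer 1..9, the delay
  ``t1`` in minutes between base and acylating-reagent addition);
* **categorical** — unordered labels (solvent identity, the "sugar" task
  variable used for transfer learning).

For the Gaussian-process surrogate every candidate is mapped to a vector in
the unit hypercube: continuous parameters are affinely rescaled, ordinals are
rescaled by rank, and categoricals are one-hot encoded.  Parameters frozen
with ``fixed_value`` are omitted from the encoding.  A parameter may instead
be *pinned*: it stays in the encoding (the surrogate sees it vary across
historical records) but suggestions are constrained to the pinned level —
this is how the transfer-learning task variable is handled.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("rxnloop")

KINDS = ("continuous", "ordinal", "categorical")


class SpaceError(ValueError):
    """Invalid space definition or candidate."""


@dataclass(frozen=True)
class ParameterSpec:
    """One searchable reaction parameter.

    Parameters
    ----------
    name:
        Unique identifier, e.g. ``"eq_bz"``.
    kind:
        ``"continuous"``, ``"ordinal"`` or ``"categorical"``.
    lower, upper:
        Finite bounds (continuous only), in physical units.
    levels:
        Ordered distinct integers (ordinal) or ≥2 distinct labels
        (categorical).
    fixed_value:
        Optional value freezing the parameter; must lie in the domain.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    levels: tuple | None = None
    fixed_value: object = None

    def __post_init__(self):
        if not self.name or not isinstance(self.name, str):
            raise SpaceError("parameter name must be a non-empty string")
        if self.kind not in KINDS:
            raise SpaceError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.lower is None or self.upper is None:
                raise SpaceError(f"{self.name}: continuous requires bounds")
            if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
                raise SpaceError(f"{self.name}: bounds must be finite")
            if not self.lower < self.upper:
                raise SpaceError(
                    f"{self.name}: lower ({self.lower}) must be < upper ({self.upper})"
                )
            if self.levels is not None:
                raise SpaceError(f"{self.name}: continuous takes no levels")
        else:
            if self.levels is None or len(self.levels) == 0:
                raise SpaceError(f"{self.name}: {self.kind} requires levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise SpaceError(f"{self.name}: duplicate levels")
            if self.kind == "ordinal":
                if not all(isinstance(l, (int, np.integer)) for l in self.levels):
                    raise SpaceError(f"{self.name}: ordinal levels must be integers")
                if list(self.levels) != sorted(self.levels):
                    raise SpaceError(f"{self.name}: ordinal levels must be sorted")
            if (
                self.kind == "categorical"
                and len(self.levels) < 2
                and self.fixed_value is None
            ):
                raise SpaceError(f"{self.name}: categorical needs >=2 labels")
        if self.fixed_value is not None and not self.contains(self.fixed_value):
            raise SpaceError(
                f"{self.name}: fixed value {self.fixed_value!r} outside domain"
            )

    @property
    def is_fixed(self) -> bool:
        return self.fixed_value is not None

    def contains(self, value) -> bool:
        """Whether ``value`` lies in this parameter's domain."""
        if self.kind == "continuous":
            try:
                v = float(value)
            except (TypeError, ValueError):
                return False
            return self.lower - 1e-12 <= v <= self.upper + 1e-12
        if self.kind == "ordinal":
            try:
                return int(value) in self.levels and float(value) == int(value)
            except (TypeError, ValueError):
                return False
        return value in self.levels

    def sample(self, rng: np.random.Generator):
        if self.is_fixed:
            return self.fixed_value
        if self.kind == "continuous":
            return float(rng.uniform(self.lower, self.upper))
        return self.levels[int(rng.integers(len(self.levels)))]


@dataclass(frozen=True)
class Candidate:
    """One concrete set of reaction conditions."""

    values: Mapping[str, object]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name):
        return self.values[name]

    def __eq__(self, other):
        if not isinstance(other, Candidate):
            return NotImplemented
        if set(self.values) != set(other.values):
            return False
        for k, v in self.values.items():
            w = other.values[k]
            if isinstance(v, float) or isinstance(w, float):
                # tolerant to text-serialization roundtrips (12 significant digits)
                if not math.isclose(float(v), float(w), rel_tol=1e-9, abs_tol=1e-12):
                    return False
            elif v != w:
                return False
        return True

    def __hash__(self):  # frozen but dict-valued; hash by items
        return hash(tuple(sorted((k, repr(v)) for k, v in self.values.items())))


@dataclass(frozen=True)
class ReactionSpace:
    """An ordered, validated collection of :class:`ParameterSpec`.

    ``pinned`` maps parameter names to the single level that suggestions must
    take, while historical records may carry any level (used by the transfer
    task variable).
    """

    params: tuple[ParameterSpec, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)
    pinned: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))
        object.__setattr__(self, "metadata", dict(self.metadata))
        object.__setattr__(self, "pinned", dict(self.pinned))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise SpaceError("duplicate parameter names")
        if not any(not p.is_fixed for p in self.params):
            raise SpaceError("space needs at least one non-fixed parameter")
        for name, value in self.pinned.items():
            p = self[name]
            if not p.contains(value):
                raise SpaceError(f"pinned value {value!r} outside {name}'s domain")

    def __getitem__(self, name: str) -> ParameterSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.params)

    @property
    def free_params(self) -> tuple[ParameterSpec, ...]:
        return tuple(p for p in self.params if not p.is_fixed)

    @property
    def dim(self) -> int:
        """Normalized dimensionality: free continuous + free ordinal +
        one-hot blocks of free categoricals."""
        d = 0
        for p in self.free_params:
            d += len(p.levels) if p.kind == "categorical" else 1
        return d

    @property
    def onehot_mask(self) -> np.ndarray:
        """Boolean mask over normalized coordinates marking one-hot columns."""
        mask = []
        for p in self.free_params:
            if p.kind == "categorical":
                mask.extend([True] * len(p.levels))
            else:
                mask.append(False)
        return np.asarray(mask, dtype=bool)

    @property
    def continuous_mask(self) -> np.ndarray:
        mask = []
        for p in self.free_params:
            if p.kind == "categorical":
                mask.extend([False] * len(p.levels))
            else:
                mask.append(p.kind == "continuous")
        return np.asarray(mask, dtype=bool)

    # ----- candidate validation -------------------------------------------

    def validate(self, candidate: Candidate, enforce_pinned: bool = False) -> None:
        """Raise :class:`SpaceError` unless ``candidate`` is valid here."""
        for p in self.params:
            if p.name not in candidate.values:
                raise SpaceError(f"candidate missing parameter {p.name!r}")
            v = candidate.values[p.name]
            if not p.contains(v):
                raise SpaceError(f"{p.name}={v!r} outside domain")
            if p.is_fixed:
                if p.kind == "continuous":
                    if abs(float(v) - float(p.fixed_value)) > 1e-9:
                        raise SpaceError(f"{p.name} must hold fixed value")
                elif v != p.fixed_value:
                    raise SpaceError(f"{p.name} must hold fixed value")
        if enforce_pinned:
            for name, value in self.pinned.items():
                if candidate.values[name] != value:
                    raise SpaceError(f"{name} must be pinned to {value!r}")
        extra = set(candidate.values) - {p.name for p in self.params}
        if extra:
            raise SpaceError(f"unknown parameters in candidate: {sorted(extra)}")

    def is_valid(self, candidate: Candidate) -> bool:
        try:
            self.validate(candidate)
            return True
        except SpaceError:
            return False

    # ----- normalization ---------------------------------------------------

    def normalize(self, candidate: Candidate) -> np.ndarray:
        """Map a valid candidate to the unit hypercube.

        continuous → (v - lower)/(upper - lower); ordinal → rank/(L-1);
        categorical → one-hot; fixed parameters omitted.
        """
        self.validate(candidate)
        out: list[float] = []
        for p in self.free_params:
            v = candidate.values[p.name]
            if p.kind == "continuous":
                out.append((float(v) - p.lower) / (p.upper - p.lower))
            elif p.kind == "ordinal":
                idx = p.levels.index(int(v))
                out.append(idx / (len(p.levels) - 1) if len(p.levels) > 1 else 0.0)
            else:
                block = [0.0] * len(p.levels)
                block[p.levels.index(v)] = 1.0
                out.extend(block)
        return np.asarray(out, dtype=float)

    def normalize_many(self, candidates: Iterable[Candidate]) -> np.ndarray:
        return np.vstack([self.normalize(c) for c in candidates])

    def denormalize(self, x: Sequence[float]) -> Candidate:
        """Inverse of :meth:`normalize` (ordinals snapped, categoricals by
        argmax of their one-hot block)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise SpaceError(f"expected vector of length {self.dim}, got {x.shape}")
        values: dict[str, object] = {
            p.name: p.fixed_value for p in self.params if p.is_fixed
        }
        i = 0
        for p in self.free_params:
            if p.kind == "continuous":
                v = float(np.clip(x[i], 0.0, 1.0))
                values[p.name] = p.lower + v * (p.upper - p.lower)
                i += 1
            elif p.kind == "ordinal":
                L = len(p.levels)
                idx = int(round(np.clip(x[i], 0.0, 1.0) * (L - 1))) if L > 1 else 0
                values[p.name] = p.levels[idx]
                i += 1
            else:
                L = len(p.levels)
                values[p.name] = p.levels[int(np.argmax(x[i : i + L]))]
                i += L
        return Candidate(values)

    def sample(self, rng: np.random.Generator) -> Candidate:
        """Uniform random valid candidate (pinned parameters honored)."""
        values = {}
        for p in self.params:
            if p.name in self.pinned:
                values[p.name] = self.pinned[p.name]
            else:
                values[p.name] = p.sample(rng)
        return Candidate(values)


# ----- construction from configuration ------------------------------------


def build_space(config) -> ReactionSpace:
    """Build a validated :class:`ReactionSpace` from a configuration.

    ``config`` is a mapping (or a path to a YAML document) with a
    ``parameters`` list; each entry carries ``name``, ``kind`` and the
    kind-specific domain (``lower``/``upper``, or ``levels``), plus optional
    ``fixed_value``.  Top-level ``metadata`` and ``pinned`` are passed
    through.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "parameters" not in config:
        raise SpaceError("configuration must contain a 'parameters' list")
    params = []
    for entry in config["parameters"]:
        entry = dict(entry)
        name = entry.pop("name", None)
        kind = entry.pop("kind", None)
        spec = ParameterSpec(
            name=name,
            kind=kind,
            lower=entry.pop("lower", None),
            upper=entry.pop("upper", None),
            levels=entry.pop("levels", None),
            fixed_value=entry.pop("fixed_value", None),
        )
        if entry:
            raise SpaceError(f"{name}: unknown keys {sorted(entry)}")
        params.append(spec)
    return ReactionSpace(
        params=tuple(params),
        metadata=config.get("metadata", {}),
        pinned=config.get("pinned", {}),
    )


def restrict_space(
    space: ReactionSpace,
    fixes: Mapping[str, object] | None = None,
    bound_updates: Mapping[str, Mapping[str, float]] | None = None,
    added_params: Sequence[ParameterSpec] = (),
    removed_params: Sequence[str] = (),
) -> ReactionSpace:
    """Derive a child space: freeze parameters, update continuous bounds,
    add or remove parameters.

    This is how a follow-up loop narrows the search: e.g. fix the
    benzoylating reagent and base to the incumbent optimum, raise the
    eq-base upper bound, replace the solvent categorical by a continuous
    mixing-ratio parameter.
    """
    fixes = dict(fixes or {})
    bound_updates = dict(bound_updates or {})
    for name in itertools.chain(fixes, bound_updates):
        if name not in space:
            raise SpaceError(f"unknown parameter {name!r}")
    for name in removed_params:
        if name not in space:
            raise SpaceError(f"unknown parameter {name!r}")
    existing = {p.name for p in space.params if p.name not in removed_params}
    for p in added_params:
        if p.name in existing:
            raise SpaceError(f"added parameter {p.name!r} collides")
    new_params = []
    for p in space.params:
        if p.name in removed_params:
            continue
        if p.name in bound_updates:
            upd = bound_updates[p.name]
            if p.kind != "continuous":
                raise SpaceError(f"{p.name}: bound updates apply to continuous only")
            p = replace(
                p,
                lower=float(upd.get("lower", p.lower)),
                upper=float(upd.get("upper", p.upper)),
            )
        if p.name in fixes:
            value = fixes[p.name]
            if not p.contains(value):
                raise SpaceError(f"cannot fix {p.name} to out-of-domain {value!r}")
            p = replace(p, fixed_value=value)
        elif p.is_fixed and not p.contains(p.fixed_value):
            raise SpaceError(f"{p.name}: bounds shrunk below fixed value")
        new_params.append(p)
    new_params.extend(added_params)
    return ReactionSpace(
        params=tuple(new_params), metadata=dict(space.metadata), pinned=dict(space.pinned)
    )


# ----- candidate (de)serialization -----------------------------------------


def candidate_to_row(candidate: Candidate) -> dict:
    return dict(candidate.values)


def candidate_from_row(row: Mapping[str, object], space: ReactionSpace) -> Candidate:
    """Re-type a flat row (e.g. a CSV record) into a Candidate for ``space``."""
    values = {}
    for p in space.params:
        if p.name not in row or row[p.name] is None:
            raise SpaceError(f"row missing parameter {p.name!r}")
        raw = row[p.name]
        if p.kind == "continuous":
            values[p.name] = float(raw)
        elif p.kind == "ordinal":
            values[p.name] = int(float(raw))
        else:
            values[p.name] = str(raw)
    c = Candidate(values)
    space.validate(c)
    return c
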