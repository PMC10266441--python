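"""Synthetic benzoylation-yield oracle.

Stands in for the synthesis robot + UPLC: given one set of reaction
conditions it returns the fractions of the three species tracked in the
real chromatograms — unreacted glycoside, 6-O-monobenzoylated product and
3,6-di-benzoylated product — plus Gaussian measurement noise.

The chemistry is modelled as a consecutive pseudo-first-order acylation
A → B → C over the fixed 1 h reaction time, with closed form

    A(t) = exp(-k1 t)
    B(t) = k1/(k2-k1) * (exp(-k1 t) - exp(-k2 t))      (k1 t exp(-k1 t) at k1=k2)
    C(t) = 1 - A - B.

Both pseudo-rates are products of condition responses:

    k1 = k1ref * act(base) * act(eq_base) * w[reagent] * m(solvent)
              * g(conc) * sat(eq_bz) * h(t1)
    k2 = k2ref * (same responses) * supp(eq_bz)

where ``act(base)`` is a logistic gate in the PCA-ordered base integer
(strong trialkylamines at the low integers activate the reaction, the weak
pyridines do not — this produces the large zero-yield regions seen in
sparse initial designs), ``act(eq_base)`` a saturating response in base
equivalents, ``g`` a log-normal response in concentration, ``sat`` a
saturating response in benzoylating-reagent equivalents, and ``supp`` a
logistic suppression of the second acylation below ~2-3 equivalents (the
stoichiometric limit: the di-product needs excess reagent).  The mono/di
trade-off therefore emerges honestly: moderate reagent excess maximizes the
mono product, large excess drives it on to the di product.

Three substrate profiles (β-glucoside-, α-thiomannoside- and
β-galactoside-like) share this qualitative optimum family but differ in
optimum locations, solvent preferences and rates, with inter-profile yield
correlation designed to be high enough for transfer learning to help and
low enough that optima genuinely differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .space import Candidate, ReactionSpace

T_REACTION = 1.0  # hours; fixed, like temperature, by the loop design
PURE_SOLVENTS = ("MeCN", "THF", "dioxane", "toluene")
DEFAULT_PROFILE_SEED = 20230518
DEFAULT_SIGMA_MEAS = 2.0  # yield-points; chromatographic repeatability scale


def solvent_labels() -> list[str]:
    """The 10 solvent categories: 4 pure solvents + all 1:1 binary mixtures."""
    labels = list(PURE_SOLVENTS)
    for i in range(len(PURE_SOLVENTS)):
        for j in range(i + 1, len(PURE_SOLVENTS)):
            labels.append(f"{PURE_SOLVENTS[i]}/{PURE_SOLVENTS[j]}")
    return labels


@dataclass
class SubstrateProfile:
    """Ground-truth yield-surface parameters for one synthetic substrate."""

    name: str
    k1ref: float  # mono-acylation pseudo-rate scale, 1/h
    k2ref: float  # di-acylation pseudo-rate scale, 1/h
    base_mid: float  # logistic midpoint in base integer
    base_steep: float  # logistic steepness (activation falls with integer)
    eq_base_K: float  # half-saturation of the eq-base response
    reagent_weight: Mapping[int, float]  # {1: BzCl, 2: Bz2O}
    solvent_mult: Mapping[str, float]  # per pure solvent, >= 0
    mix_boost: float  # bonus multiplier for 1:1 mixtures
    conc_opt: float  # mol/L
    conc_width: float  # log-scale width
    eqbz_K1: float  # half-saturation of eq-Bz for the first acylation
    eqbz_supp_mid: float  # eq-Bz midpoint of the di suppression logistic
    eqbz_supp_steep: float
    t1_opt: float  # minutes
    t1_width: float
    t1_floor: float
    base_bumps: Mapping[int, float] = field(default_factory=dict)  # catalytic bases
    texture_amp: float = 0.0  # substrate-idiosyncrasy amplitude (log-rate scale)
    texture_seed: int = 0
    sigma_meas: float = DEFAULT_SIGMA_MEAS
    recorded_max: dict = field(default_factory=dict)  # (space, objective) -> %

    def __post_init__(self):
        if self.k1ref < 0 or self.k2ref < 0 or self.sigma_meas < 0:
            raise ValueError("rates and noise must be non-negative")
        if any(v < 0 for v in self.solvent_mult.values()):
            raise ValueError("solvent multipliers must be non-negative")
        if any(v < 0 for v in self.reagent_weight.values()):
            raise ValueError("reagent weights must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reagent_weight"] = {int(k): v for k, v in self.reagent_weight.items()}
        d["recorded_max"] = {f"{k[0]}|{k[1]}": v for k, v in self.recorded_max.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubstrateProfile":
        d = dict(d)
        d["reagent_weight"] = {int(k): v for k, v in d["reagent_weight"].items()}
        d["recorded_max"] = {
            tuple(k.split("|")): v for k, v in d.get("recorded_max", {}).items()
        }
        return cls(**d)


# ----- condition responses (vectorized) ------------------------------------


def _solvent_multiplier(profile: SubstrateProfile, labels=None, ratio=None):
    """k multiplier from the solvent, either categorical (``labels``) or as a
    continuous MeCN:THF mixing ratio (0 = MeCN, 1 = THF)."""
    if ratio is not None:
        r = np.asarray(ratio, dtype=float)
        m_a = profile.solvent_mult["MeCN"]
        m_b = profile.solvent_mult["THF"]
        log_m = (1.0 - r) * np.log(max(m_a, 1e-12)) + r * np.log(max(m_b, 1e-12))
        return np.exp(log_m) * (1.0 + profile.mix_boost * 4.0 * r * (1.0 - r))
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(np.asarray(labels, dtype=object)):
        if "/" in lab:
            a, b = lab.split("/")
            out[i] = np.sqrt(
                profile.solvent_mult[a] * profile.solvent_mult[b]
            ) * (1.0 + profile.mix_boost)
        else:
            out[i] = profile.solvent_mult[lab]
    return out


_N_TEXTURE = 8


def _texture(profile: SubstrateProfile, v: Mapping[str, np.ndarray], n: int):
    """Smooth substrate-specific multiplier exp(amp · z), z a seeded
    random-Fourier field over every condition except eq-Bz (so conversion
    stays monotone in reagent equivalents).  Models the idiosyncrasies that
    make optima substrate-specific beyond the shared response family."""
    if profile.texture_amp == 0.0:
        return np.ones(n)
    rng = np.random.default_rng(profile.texture_seed)
    # coarse normalized coordinates of the texture-relevant conditions
    u = np.column_stack(
        [
            np.asarray(v["eq_base"], dtype=float) / 30.0,
            np.asarray(v["conc"], dtype=float) / 0.2,
            np.asarray(v["t1"], dtype=float) / 20.0,
            np.asarray(v["base"], dtype=float) / 9.0,
        ]
    )
    omega = rng.uniform(0.5, 2.0, size=(_N_TEXTURE, u.shape[1])) * 2.0 * np.pi
    phase = rng.uniform(0.0, 2.0 * np.pi, size=_N_TEXTURE)
    amp = rng.normal(0.0, 1.0, size=_N_TEXTURE)
    z = (np.cos(u @ omega.T + phase) * amp).sum(axis=1) / np.sqrt(_N_TEXTURE)
    # per-level offsets for the discrete identity conditions
    z = z + 0.3 * rng.normal(0.0, 1.0, size=2)[
        np.asarray(v["bz_reagent"], dtype=int) - 1
    ]
    if "solvent" in v:
        labels = solvent_labels()
        offs = rng.normal(0.0, 1.0, size=len(labels))
        idx = {lab: i for i, lab in enumerate(labels)}
        z = z + 0.15 * np.array(
            [offs[idx[str(lab)]] for lab in np.atleast_1d(v["solvent"])]
        )
    else:
        offs = rng.normal(0.0, 1.0, size=2)  # endpoints of the MeCN:THF ratio
        r = np.asarray(v["solvent_ratio"], dtype=float)
        z = z + 0.15 * ((1.0 - r) * offs[0] + r * offs[1])
    # clip the field: substrate idiosyncrasies modulate, but do not create
    # needle-like spikes that would dominate the recorded global maxima
    return np.exp(profile.texture_amp * np.clip(z, -1.0, 1.0))


def _rates(profile: SubstrateProfile, v: Mapping[str, np.ndarray]):
    """Vectorized (k1, k2) from arrays of condition values."""
    eq_bz = np.asarray(v["eq_bz"], dtype=float)
    eq_base = np.asarray(v["eq_base"], dtype=float)
    conc = np.asarray(v["conc"], dtype=float)
    base = np.asarray(v["base"], dtype=float)
    bz = np.asarray(v["bz_reagent"])
    t1 = np.asarray(v["t1"], dtype=float)

    act_base = 1.0 / (1.0 + np.exp(profile.base_steep * (base - profile.base_mid)))
    if profile.base_bumps:
        # substrate-specific catalytic bases (e.g. nucleophilic catalysis)
        bump = np.zeros_like(act_base)
        for level, boost in profile.base_bumps.items():
            bump = bump + boost * (base == level)
        act_base = np.clip(act_base + bump, 0.0, 1.0)
    act_eq = eq_base**2 / (eq_base**2 + profile.eq_base_K**2)
    w = np.array([profile.reagent_weight[int(b)] for b in np.atleast_1d(bz)])
    if "solvent_ratio" in v:
        m = _solvent_multiplier(profile, ratio=v["solvent_ratio"])
    else:
        m = _solvent_multiplier(profile, labels=np.atleast_1d(v["solvent"]))
    g = np.exp(-0.5 * (np.log(conc / profile.conc_opt) / profile.conc_width) ** 2)
    sat = eq_bz / (eq_bz + profile.eqbz_K1)
    h = profile.t1_floor + (1.0 - profile.t1_floor) * np.exp(
        -0.5 * ((t1 - profile.t1_opt) / profile.t1_width) ** 2
    )
    tex = _texture(profile, v, eq_base.size)
    common = act_base * act_eq * w * g * h * tex
    k1 = profile.k1ref * common * m * sat
    supp = 1.0 / (
        1.0 + np.exp(-profile.eqbz_supp_steep * (eq_bz - profile.eqbz_supp_mid))
    )
    # the second acylation is much less solvent-sensitive than the first
    # (m^0.3): without this, at full conversion the di-leak would scale with
    # the same solvent factor and the weakest converting solvent would win
    k2 = profile.k2ref * common * np.power(np.maximum(m, 1e-12), 0.3) * supp
    return k1, k2


def consecutive_fractions(k1, k2, t: float = T_REACTION):
    """Closed-form species fractions of A -> B -> C at time ``t``."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    a = np.exp(-k1 * t)
    close = np.abs(k1 - k2) < 1e-9 * np.maximum(k1, 1.0)
    denom = np.where(close, 1.0, k2 - k1)
    b_generic = k1 / denom * (np.exp(-k1 * t) - np.exp(-k2 * t))
    b_equal = k1 * t * np.exp(-k1 * t)
    b = np.where(close, b_equal, b_generic)
    b = np.clip(b, 0.0, 1.0)
    c = np.clip(1.0 - a - b, 0.0, 1.0)
    return a, b, c


def species_fractions_batch(
    values: Mapping[str, np.ndarray], profile: SubstrateProfile
):
    """Vectorized (reactant, mono, di) fractions for arrays of conditions."""
    k1, k2 = _rates(profile, values)
    return consecutive_fractions(k1, k2)


def species_fractions(
    candidate: Candidate | Mapping[str, object], profile: SubstrateProfile
) -> tuple[float, float, float]:
    """Noise-free (reactant, mono, di) fractions for one candidate.

    Fractions are non-negative and sum to 1; conditions where the base gate
    is shut give reactant ≈ 1 (the zero-yield dead zones)."""
    values = candidate.values if isinstance(candidate, Candidate) else candidate
    arrays = {k: np.atleast_1d(np.asarray(v)) for k, v in values.items()}
    a, b, c = species_fractions_batch(arrays, profile)
    return float(a[0]), float(b[0]), float(c[0])


def measure(
    fractions,
    objective: str,
    sigma_meas: float,
    seed: int | np.random.Generator = 0,
) -> float:
    """Observed yield-percent: 100 × fraction(objective) + N(0, σ²), clipped
    to [0, 100].  ``objective`` is ``"mono"`` or ``"di"``."""
    reactant, mono, di = fractions
    if objective == "mono":
        y = 100.0 * mono
    elif objective == "di":
        y = 100.0 * di
    else:
        raise ValueError(f"unknown objective {objective!r}")
    if sigma_meas > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        y += rng.normal(0.0, sigma_meas)
    return float(np.clip(y, 0.0, 100.0))


# ----- batch sampling / dense search ---------------------------------------


def sample_batch(space: ReactionSpace, n: int, rng: np.random.Generator):
    """n uniform random candidates as a dict of arrays (fast path for dense
    search; pinned/fixed parameters held)."""
    out: dict[str, np.ndarray] = {}
    for p in space.params:
        if p.name in space.pinned:
            out[p.name] = np.full(n, space.pinned[p.name], dtype=object)
        elif p.is_fixed:
            out[p.name] = np.full(
                n,
                p.fixed_value,
                dtype=float if p.kind == "continuous" else object,
            )
        elif p.kind == "continuous":
            out[p.name] = rng.uniform(p.lower, p.upper, size=n)
        else:
            out[p.name] = np.asarray(p.levels, dtype=object)[
                rng.integers(len(p.levels), size=n)
            ]
    return out


def noise_free_max(
    profile: SubstrateProfile,
    space: ReactionSpace,
    objective: str,
    n: int = 100_000,
    seed: int = 0,
    polish: bool = True,
) -> tuple[float, Candidate]:
    """Noise-free global maximum over ``space`` by dense random search with a
    local polish of the continuous coordinates of the best hit."""
    rng = np.random.default_rng(seed)
    values = sample_batch(space, n, rng)
    a, b, c = species_fractions_batch(values, profile)
    y = 100.0 * (b if objective == "mono" else c)
    best = int(np.argmax(y))
    cand_values = {}
    for p in space.params:
        v = values[p.name][best]
        if p.kind == "continuous":
            cand_values[p.name] = float(v)
        elif p.kind == "ordinal":
            cand_values[p.name] = int(v)
        else:
            cand_values[p.name] = v
    best_y = float(y[best])
    if polish:
        cont = [p for p in space.params if p.kind == "continuous" and not p.is_fixed]
        if cont:

            def neg(xs):
                trial = dict(cand_values)
                for p, x in zip(cont, xs):
                    trial[p.name] = float(np.clip(x, p.lower, p.upper))
                _, mono, di = species_fractions(trial, profile)
                return -100.0 * (mono if objective == "mono" else di)

            res = minimize(
                neg,
                [cand_values[p.name] for p in cont],
                method="Nelder-Mead",
                options={"maxfev": 400, "xatol": 1e-4, "fatol": 1e-6},
            )
            if -res.fun > best_y:
                best_y = float(-res.fun)
                for p, x in zip(cont, res.x):
                    cand_values[p.name] = float(np.clip(x, p.lower, p.upper))
    return best_y, Candidate(cand_values)


# ----- the three study profiles --------------------------------------------


def _derive_texture_seed(seed: int, k: int) -> int:
    return int(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11 * (k + 1)]).generate_state(1)[
            0
        ]
        % (2**31)
    )


def make_profiles(seed: int = DEFAULT_PROFILE_SEED) -> dict[str, SubstrateProfile]:
    """Three deterministic substrate profiles sharing the strong-amine +
    anhydride + excess-reagent optimum family but differing in optimum
    locations (concentration, solvent preference, t1, rates)."""
    rng = np.random.default_rng(seed)

    def jitter(scale=0.05):
        return float(1.0 + rng.normal(0.0, scale))

    profiles = {}
    base_specs = {
        "glucoside": dict(
            k1ref=12.0,
            k2ref=1.2,
            base_mid=3.1,
            base_steep=3.0,
            eq_base_K=15.0,
            reagent_weight={1: 0.25, 2: 1.0},
            solvent_mult={"MeCN": 0.6, "THF": 0.95, "dioxane": 0.06, "toluene": 0.03},
            mix_boost=0.10,
            conc_opt=0.10,
            conc_width=0.40,
            eqbz_K1=1.2,
            eqbz_supp_mid=4.5,
            eqbz_supp_steep=3.0,
            t1_opt=3.0,
            t1_width=8.0,
            t1_floor=0.3,
            texture_amp=0.7,
        ),
        "thiomannoside": dict(
            k1ref=11.0,
            k2ref=0.8,
            base_mid=2.4,
            base_steep=3.0,
            eq_base_K=12.0,
            reagent_weight={1: 0.8, 2: 1.0},
            solvent_mult={"MeCN": 0.08, "THF": 0.95, "dioxane": 0.5, "toluene": 0.08},
            mix_boost=0.05,
            conc_opt=0.05,
            conc_width=0.50,
            eqbz_K1=1.6,
            eqbz_supp_mid=4.5,
            eqbz_supp_steep=1.8,
            t1_opt=18.0,
            t1_width=9.0,
            t1_floor=0.65,
            base_bumps={6: 0.5, 8: 0.15},
            texture_amp=0.45,
        ),
        "galactoside": dict(
            k1ref=5.5,
            k2ref=2.6,
            base_mid=4.0,
            base_steep=2.4,
            eq_base_K=7.0,
            reagent_weight={1: 0.15, 2: 1.0},
            solvent_mult={"MeCN": 0.15, "THF": 0.55, "dioxane": 0.95, "toluene": 0.3},
            mix_boost=0.1,
            conc_opt=0.13,
            conc_width=0.35,
            eqbz_K1=1.0,
            eqbz_supp_mid=5.0,
            eqbz_supp_steep=2.4,
            t1_opt=14.0,
            t1_width=7.0,
            t1_floor=0.35,
            base_bumps={8: 0.2},
            texture_amp=0.7,
        ),
    }
    for k, (name, spec) in enumerate(base_specs.items()):
        spec = dict(spec)
        for key in ("k1ref", "k2ref", "conc_opt"):
            spec[key] = spec[key] * jitter(0.03)
        spec["texture_seed"] = _derive_texture_seed(seed, k)
        profiles[name] = SubstrateProfile(name=name, **spec)

    from .configs import load_space  # local import: configs depends on space only

    for space_name in ("cl1", "transfer"):
        space = load_space(space_name)
        for name, profile in profiles.items():
            if space_name == "transfer":
                space_p = ReactionSpace(
                    params=space.params,
                    metadata=space.metadata,
                    pinned={"sugar": profile_task_label(name)},
                )
            else:
                space_p = space
            for objective in ("mono", "di"):
                y, _ = noise_free_max(
                    profile, space_p, objective, n=100_000, seed=seed + 1
                )
                profile.recorded_max[(space_name, objective)] = y
    return profiles


def profile_task_label(profile_name: str) -> str:
    return {
        "glucoside": "beta-glucoside",
        "thiomannoside": "alpha-thiomannoside",
        "galactoside": "beta-galactoside",
    }[profile_name]
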