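import warnings

import numpy as np
import pytest

import rxnloop as rl

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def cl1_space():
    return rl.configs.load_space("cl1")


@pytest.fixture(scope="session")
def transfer_space():
    return rl.configs.load_space("transfer")


@pytest.fixture(scope="session")
def profiles():
    return rl.make_profiles()


@pytest.fixture(scope="session")
def tiny_space():
    """A 4-parameter mixed space small enough for fast closed loops."""
    return rl.build_space(
        {
            "parameters": [
                {"name": "eq_bz", "kind": "continuous", "lower": 1.0, "upper": 4.0},
                {"name": "eq_base", "kind": "continuous", "lower": 1.0, "upper": 16.7},
                {"name": "conc", "kind": "continuous", "lower": 0.04, "upper": 0.15},
                {"name": "bz_reagent", "kind": "ordinal", "levels": [1, 2]},
                {"name": "base", "kind": "ordinal", "levels": list(range(1, 10))},
                {"name": "t1", "kind": "ordinal", "levels": [0, 5, 10, 15, 20]},
                {
                    "name": "solvent",
                    "kind": "categorical",
                    "levels": ["MeCN", "THF", "dioxane"],
                },
            ]
        }
    )


def random_space(rng: np.random.Generator) -> rl.ReactionSpace:
    """A random small mixed space, for fuzzing."""
    params = []
    n_cont = rng.integers(1, 3)
    for i in range(n_cont):
        lo = float(rng.uniform(-5, 5))
        params.append(
            rl.ParameterSpec(f"c{i}", "continuous", lower=lo, upper=lo + float(rng.uniform(0.5, 10)))
        )
    for i in range(rng.integers(0, 3)):
        n = int(rng.integers(2, 6))
        params.append(
            rl.ParameterSpec(f"o{i}", "ordinal", levels=sorted(rng.choice(50, n, replace=False).tolist()))
        )
    for i in range(rng.integers(0, 2)):
        n = int(rng.integers(2, 5))
        params.append(
            rl.ParameterSpec(f"k{i}", "categorical", levels=[f"L{j}" for j in range(n)])
        )
    return rl.ReactionSpace(params=tuple(params))
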