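"""Packaged reaction-space configuration fixtures (YAML)."""

from importlib import resources

import yaml

from ..space import ReactionSpace, build_space

__all__ = ["load_space", "load_config", "available"]


def available() -> list[str]:
    return sorted(
        p.name[:-5]
        for p in resources.files(__package__).iterdir()
        if p.name.endswith(".yaml")
    )


def load_config(name: str) -> dict:
    path = resources.files(__package__) / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(f"no packaged config {name!r}; have {available()}")
    return yaml.safe_load(path.read_text())


def load_space(name: str) -> ReactionSpace:
    """Load one of the packaged spaces (``cl1``, ``cl2``, ``cl3``,
    ``transfer``) as a validated :class:`ReactionSpace`."""
    return build_space(load_config(name))
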