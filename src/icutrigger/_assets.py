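"""Loading of the packaged YAML configuration assets."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml


@lru_cache(maxsize=None)
def load_asset(name: str) -> dict:
    """Load a packaged YAML asset by file name (cached)."""
    ref = resources.files("icutrigger.assets").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
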