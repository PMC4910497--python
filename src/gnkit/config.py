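"""Loading of the editable vocabularies, rules and weights.

Every behavioural knob of the toolkit — rank-marker and annotation
vocabularies for the parser, repair rules for the preprocessor, term
vocabularies for the classifier, point weights for the scorer — lives in
YAML files so each can be adapted per source without touching code.  The
packaged defaults are seeded from the published term lists; all of them
are open-ended and meant to be extended as new pathologies are met.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def _read_packaged(filename: str) -> str:
    return resources.files("gnkit.data").joinpath(filename).read_text(encoding="utf-8")


@functools.lru_cache(maxsize=None)
def load_default(filename: str) -> Any:
    """Load a packaged YAML/text config file (cached)."""
    text = _read_packaged(filename)
    if filename.endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return text


def load_yaml(path: str | Path | None, default_filename: str) -> Any:
    """Load YAML from *path*, falling back to the packaged default."""
    if path is None:
        return load_default(default_filename)
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
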