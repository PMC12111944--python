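"""Load the packaged defaults file once at import time."""

from __future__ import annotations

from importlib import resources

import yaml


def _load() -> dict:
    text = resources.files("hepindex").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


DEFAULTS: dict = _load()
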