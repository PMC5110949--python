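"""Load the bundled model definition files (parameters + initial states)."""
from __future__ import annotations

from importlib import resources

import yaml


def load_model_file(filename: str) -> dict:
    ref = resources.files(__package__) / "data" / filename
    with ref.open("r") as fh:
        return yaml.safe_load(fh)
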