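"""Access to packaged data files (parameter tables and printed-table fixtures)."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(files("aptascreen").joinpath("data", name)))
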