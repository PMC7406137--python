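"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def truncated_percent(numerator: int, denominator: int) -> int:
    """Percentage truncated toward zero, as conventionally printed in gene
    tallies (e.g. 11 of 17 genes up-regulated -> 64%)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return int(100 * numerator / denominator)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
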