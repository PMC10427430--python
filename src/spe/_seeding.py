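"""Deterministic per-stage random substreams.

One global seed fans out to named streams so that adding a stage to a
pipeline never shifts the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for stage ``name`` derived from the global ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
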