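"""Deterministic seed-substream derivation.

Every stochastic stage derives its own substream from a single master seed by
a stable, documented rule, so a cohort is a pure function of (config, seed)
and any single subject/stream can be regenerated in isolation:

    substream = first 4 bytes of sha256("master:subject_id:stream_name"),
    interpreted big-endian and truncated to 31 bits.

sha256 is stable across platforms and Python versions (unlike ``hash()``).
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(master: int, subject_id: int | str, stream: str) -> int:
    key = f"{master}:{subject_id}:{stream}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def substream_rng(master: int, subject_id: int | str, stream: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master, subject_id, stream))
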