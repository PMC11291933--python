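"""Seed plumbing: one root seed fans out into named substreams so each
stage (metadata, each omics space, rarefaction, ...) can be regenerated
independently and deterministically."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for ``name`` derived from the root ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
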