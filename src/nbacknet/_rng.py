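"""Deterministic, label-keyed random substreams.

Substreams are keyed by stable CRC-32 hashes of identifying labels
(subject id, condition, band, role) together with the integer master
seed, so regenerating a cohort with more subjects, or analyzing cells
in a different order, never perturbs the draws of existing cells.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(*parts) -> np.random.Generator:
    entropy = [p if isinstance(p, (int, np.integer))
               else zlib.crc32(str(p).encode())
               for p in parts]
    return np.random.default_rng(np.random.SeedSequence(entropy))
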