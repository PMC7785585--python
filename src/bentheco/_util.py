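"""Shared helpers: seed derivation and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("bentheco")


def derive_seed(global_seed: int, label: str) -> int:
    """Derive a stage-specific sub-seed from a global seed and a stage label.

    The derivation is a stable hash, so adding a new stage never perturbs
    the random streams of existing stages.  The result fits in 31 bits.
    """
    digest = hashlib.blake2s(f"{global_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
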