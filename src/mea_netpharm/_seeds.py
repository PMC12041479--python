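"""Deterministic seed fan-out.

A single master seed is expanded into independent per-stage seeds by hashing
the stage name together with any identifying strings (chip id, condition,
window index, method ...).  This makes every stage individually reproducible
without threading RNG state through the pipeline.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *parts: object) -> int:
    """Derive a 31-bit seed from ``master_seed`` and identifying parts."""
    payload = "|".join([str(int(master_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
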