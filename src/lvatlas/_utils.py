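"""Provenance and seeding helpers."""

from __future__ import annotations

import hashlib
import json

import numpy as np

__all__ = ["config_hash", "derive_seed"]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-module substream seed (< 2**31) from a master seed."""
    h = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, label))
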