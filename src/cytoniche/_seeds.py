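"""Seed fan-out: one global seed deterministically spawns named child streams."""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def child_seed(seed: int, name: str) -> int:
    """Derive a reproducible child seed (< 2^31) from a global seed and a label."""
    ss = np.random.SeedSequence([int(seed), *name.encode("utf-8")])
    return int(ss.generate_state(1)[0]) % _MOD


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Generator for the named child stream of ``seed``."""
    return np.random.default_rng(child_seed(seed, name))
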