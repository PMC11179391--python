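"""Seed fan-out: one master seed expands to named, independent RNG streams.

Every stochastic stage (cohort draw, center assignment, minibatching, DP noise,
ELBO sampling, posterior draws, ...) pulls its own generator via a stable name,
so re-running any stage with the same (seed, name) is bitwise reproducible and
stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]

_MOD = 2**31 - 1


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream under a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic integer sub-seed (< 2^31) for a named sub-task."""
    ss = np.random.SeedSequence([int(seed), _name_key(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % _MOD)
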