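"""Deterministic seed derivation shared by all stochastic stages.

Every stage draws from its own :class:`numpy.random.Generator`, seeded by an
integer derived from the run's ``base_seed`` plus a tuple of string/int labels
(stage name, surface index, repeat index, ...).  Derived seeds are plain 31-bit
integers so they can be recorded verbatim in run manifests.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "spawn_rng"]


def _label_key(parts: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(p).encode("utf-8")) for p in parts)


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a reproducible 31-bit child seed from ``base_seed`` and labels.

    The mapping is injective enough for practical purposes (SeedSequence mixes
    the spawn key cryptographically) and stable across platforms and sessions.
    """
    ss = np.random.SeedSequence(int(base_seed), spawn_key=_label_key(parts))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def spawn_rng(base_seed: int, *parts) -> np.random.Generator:
    """Return a fresh Generator for the stage identified by ``parts``."""
    return np.random.default_rng(derive_seed(base_seed, *parts))
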