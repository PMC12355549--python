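"""Seed fan-out: one user seed, named independent substreams per component.

Every stochastic routine in the package accepts either an integer seed or a
:class:`numpy.random.Generator`.  Pipelines derive one substream per stage by
name, so enabling or disabling a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is ``(seed, crc32(name))`` fed to a ``SeedSequence``, so the
    mapping is stable across runs, platforms and Python hash randomisation.
    """
    if not 0 <= int(seed) < 2**31:
        raise ValueError(f"seed must be in [0, 2^31): {seed!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))
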