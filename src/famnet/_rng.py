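"""Named random-number streams derived from a single master seed.

Every stochastic component (wiring, membrane resets/noise, stimulus
encoding, analysis resampling) draws from its own stream so that, e.g.,
network wiring is reproducible independently of how many dynamics steps
were run.  Streams are derived with ``numpy.random.SeedSequence`` keyed by
a stable hash of the stream name plus an integer index, so any stream can
be re-derived from the master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_seed", "stream_rng"]


def stream_seed(master_seed: int, name: str, index: int = 0) -> int:
    """Return a deterministic child seed (< 2**31) for a named stream."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key, int(index)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def stream_rng(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a ``numpy`` Generator for a named stream."""
    return np.random.default_rng(stream_seed(master_seed, name, index))
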