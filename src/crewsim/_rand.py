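"""Buffered scalar draws from a numpy Generator.

Per-event simulation code needs millions of scalar uniforms; drawing them
one at a time through the Generator API dominates the runtime.  A
``DrawBuffer`` pre-draws chunks and hands out scalars; results remain fully
deterministic for a given seed because refills consume the same underlying
stream in the same order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DrawBuffer", "BufferedUniform"]


class DrawBuffer:
    """Chunked scalar uniforms (and derived small integers)."""

    __slots__ = ("_buf", "_i", "chunk")

    def __init__(self, chunk: int = 8192):
        self.chunk = chunk
        self._buf: np.ndarray | None = None
        self._i = chunk

    def uniform(self, rng: np.random.Generator) -> float:
        i = self._i
        if i >= self.chunk:
            self._buf = rng.random(self.chunk)
            i = 0
        self._i = i + 1
        return float(self._buf[i])

    def integer(self, rng: np.random.Generator, n: int) -> int:
        """Uniform integer in [0, n); floor-of-uniform (bias ~2^-53)."""
        return int(self.uniform(rng) * n)


class BufferedUniform:
    """Minimal Generator-like adapter exposing ``random()`` from a buffer."""

    __slots__ = ("_buf", "_rng")

    def __init__(self, buf: DrawBuffer, rng: np.random.Generator):
        self._buf = buf
        self._rng = rng

    def random(self) -> float:
        return self._buf.uniform(self._rng)
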