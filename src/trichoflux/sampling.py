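"""Deterministic grids and seeded random draws that feed the sweeps.

The analysis consumes parameters, not measurements: the only stochastic
input is the set of uniformly drawn trichome respiration rates in the
unequal-respiration scenario.  Everything here is reproducible — a grid
is a pure function of (start, stop, step) and a sampler of
(low, high, n, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SweepGrid", "UniformSampler", "make_grid", "substream_seed"]

_GRID_TOL = 1e-9  # relative slack when counting grid points


@dataclass(frozen=True)
class SweepGrid:
    """Inclusive arithmetic sweep ``start, start+step, …, stop``.

    Alternatively an explicit ``values`` list may be given, in which
    case start/stop/step are ignored.
    """

    name: str
    start: float = 0.0
    stop: float = 0.0
    step: float = 1.0
    values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.values is not None:
            if len(self.values) == 0:
                raise ValueError("explicit value list must be non-empty")
            return
        if self.step <= 0:
            raise ValueError("step must be strictly positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    def to_dict(self) -> dict:
        if self.values is not None:
            return {"name": self.name, "values": [float(v) for v in self.values]}
        return {
            "name": self.name,
            "start": self.start,
            "stop": self.stop,
            "step": self.step,
        }


def make_grid(spec: SweepGrid) -> np.ndarray:
    """Materialize a :class:`SweepGrid` as a float array.

    Values are built index-wise as ``start + k·step`` (never by repeated
    addition) so every point is within 1e−12 of the ideal arithmetic
    sequence on any platform.  Length is ``round((stop−start)/step) + 1``
    when the span is a whole number of steps, otherwise the last partial
    step is dropped.
    """
    if spec.values is not None:
        return np.asarray(spec.values, dtype=float)
    span = spec.stop - spec.start
    n = int(np.floor(span / spec.step + _GRID_TOL))
    return spec.start + spec.step * np.arange(n + 1)


@dataclass(frozen=True)
class UniformSampler:
    """Seeded uniform draws on [low, high)."""

    low: float
    high: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("require low < high")
        if self.n <= 0:
            raise ValueError("require n > 0")

    def draw(self) -> np.ndarray:
        """Return ``n`` uniform values; identical fields give identical draws."""
        rng = np.random.default_rng(self.seed)
        return rng.uniform(self.low, self.high, self.n)


def substream_seed(master_seed: int, label: str) -> int:
    """Derive a reproducible per-scenario seed (< 2³¹) from a master seed.

    Labelled substreams let each scenario be rerun independently of the
    others while all deriving from one top-level seed.
    """
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), key])
    return int(ss.generate_state(1)[0] % (2**31))
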