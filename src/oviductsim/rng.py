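"""Counter-based random streams for order-invariant agent simulation.

Each agent owns an independent stream keyed by ``(master_seed, agent_id)``;
a draw is addressed by ``(step, channel)``. Because every variate is a pure
hash of its address, results do not depend on how agents are batched or in
which order they are stepped — the reproducibility contract the transport
engine guarantees. The mix function is splitmix64, applied twice with
channel/step tweaks (numpy's Generator API does not expose vectorized
keyed per-agent streams, so this tiny primitive is provided here).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U53 = np.uint64(0x1FFFFFFFFFFFFF)  # 2**53 - 1


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _GOLDEN).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= _MIX1
    x ^= x >> np.uint64(27)
    x *= _MIX2
    x ^= x >> np.uint64(31)
    return x


class CounterRNG:
    """Vectorized keyed RNG: variate = hash(master_seed, agent, step, channel)."""

    def __init__(self, master_seed: int, n_agents: int):
        if not (0 <= master_seed < 2**63):
            raise ValueError("master_seed must be a non-negative 63-bit integer")
        self.master_seed = int(master_seed)
        self.n_agents = int(n_agents)
        ids = np.arange(n_agents, dtype=np.uint64)
        # per-agent base keys, decorrelated from the raw seed
        with np.errstate(over="ignore"):
            self._keys = _splitmix64(np.uint64(master_seed) ^ (ids * _MIX2))

    def _raw(self, step: int, channel: int) -> np.ndarray:
        with np.errstate(over="ignore"):
            tweak = (np.uint64(step) * _MIX1) ^ (np.uint64(channel) * _GOLDEN)
            return _splitmix64(self._keys ^ _splitmix64(np.full(
                self.n_agents, tweak, dtype=np.uint64)))

    def uniform(self, step: int, channel: int) -> np.ndarray:
        """U(0, 1) open at both ends (53-bit mantissa)."""
        u = (self._raw(step, channel) & _U53).astype(np.float64) / float(2**53)
        return np.clip(u, 1e-16, 1.0 - 1e-16)

    def normal(self, step: int, channel: int) -> np.ndarray:
        """Standard normal via the inverse CDF of a uniform draw."""
        return ndtri(self.uniform(step, channel))


def spawn_seed(master_seed: int, *tags: int) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and integer tags."""
    x = np.array([master_seed], dtype=np.uint64)
    with np.errstate(over="ignore"):
        for t in tags:
            x = _splitmix64(x ^ (np.uint64(t) * _MIX1))
    return int(x[0] & np.uint64(0x7FFFFFFF))
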