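"""Seeded gradient-stream generators implementing the sampler contract.

These streams stand in for molecular-dynamics output in tests and
examples, emulating the statistical behaviors a dV/dlambda series can
exhibit: white noise (well-behaved window), AR(1) autocorrelation
(slow configurational sampling), an exponentially decaying transient
(insufficient equilibration), time-growing variance (persistent
non-convergence) and two-state switching (conformational flipping).

Generation is counter-based: the value at sample index i depends only
on (seed, i), so concatenating ``extend`` calls yields the same stream
no matter how the total duration is partitioned — a requirement for
controller runs to be reproducible across protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import ndtri

__all__ = ["GeneratorSpec", "SyntheticSampler", "make_sampler", "stream_determinism_check"]

_KINDS = ("iid_gaussian", "ar1", "transient", "heteroscedastic", "two_state")

# numpy's Philox advance() steps the counter in blocks of 4 outputs
_PHILOX_BLOCK = 4


def _indexed_normals(seed: int, start: int, n: int) -> np.ndarray:
    """Standard normals for sample indices [start, start + n), a pure
    function of (seed, index)."""
    if n == 0:
        return np.empty(0)
    bg = np.random.Philox(key=seed)
    bg.advance(start // _PHILOX_BLOCK)
    offset = start % _PHILOX_BLOCK
    raw = bg.random_raw(offset + n)[offset:]
    u = (raw.astype(np.float64) + 0.5) / 2.0**64  # uniforms in (0, 1)
    return ndtri(u)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic gradient stream.

    Attributes
    ----------
    kind : str
        One of iid_gaussian, ar1, transient, heteroscedastic, two_state.
    mean : float
        Baseline gradient mean, kcal/mol.
    sigma : float
        Noise standard deviation, kcal/mol.
    phi : float
        AR(1) coefficient in [0, 1) (ar1 kind only).
    transient_height : float
        Initial offset of the equilibration transient, kcal/mol; for
        the two_state kind this doubles as the +/- state offset.
    transient_length : float
        e-folding time of the transient decay, ns.
    sigma_doubling_time : float
        Time over which sigma doubles (heteroscedastic kind), ns.
    switch_period : float
        Dwell time per state (two_state kind), ns.
    sampling_interval : float
        Time between samples, ns.
    seed : int
        Stream seed; same seed, same stream.
    """

    kind: str
    mean: float = 0.0
    sigma: float = 1.0
    phi: float = 0.0
    transient_height: float = 0.0
    transient_length: float = 1.0
    sigma_doubling_time: float = 1.0
    switch_period: float = 1.0
    sampling_interval: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; valid: {', '.join(_KINDS)}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")


class SyntheticSampler:
    """Stateful gradient stream satisfying the sampler contract.

    ``extend(duration)`` returns the next ``round(duration / dt)``
    samples; repeated calls append contiguously in time.
    """

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        self._next_index = 0
        self._ar_state: float | None = None

    @property
    def seed(self) -> int:
        return self.spec.seed

    @property
    def sampling_interval(self) -> float:
        return self.spec.sampling_interval

    @property
    def total_generated(self) -> float:
        """Total stream time generated so far, ns."""
        return self._next_index * self.spec.sampling_interval

    def extend(self, duration: float) -> np.ndarray:
        """Generate the next ``duration`` ns of gradient samples."""
        s = self.spec
        n = int(round(duration / s.sampling_interval))
        if n < 0:
            raise ValueError("duration must be nonnegative")
        start = self._next_index
        idx = np.arange(start, start + n)
        t = idx * s.sampling_interval
        eps = _indexed_normals(s.seed, start, n)

        if s.kind == "iid_gaussian":
            out = s.mean + s.sigma * eps
        elif s.kind == "ar1":
            out = self._ar1(eps)
        elif s.kind == "transient":
            out = s.mean + s.transient_height * np.exp(-t / s.transient_length) + s.sigma * eps
        elif s.kind == "heteroscedastic":
            out = s.mean + s.sigma * 2.0 ** (t / s.sigma_doubling_time) * eps
        else:  # two_state
            state = 1.0 - 2.0 * (np.floor(t / s.switch_period).astype(int) % 2)
            out = s.mean + s.transient_height * state + s.sigma * eps

        self._next_index = start + n
        return out

    def _ar1(self, eps: np.ndarray) -> np.ndarray:
        # x_i = mean + phi*(x_{i-1} - mean) + sqrt(1-phi^2)*sigma*eps_i,
        # stationary start x_0 = mean + sigma*eps_0; only the last state
        # crosses extend() calls, so partition invariance holds.
        s = self.spec
        out = np.empty(eps.size)
        innov = np.sqrt(1.0 - s.phi**2) * s.sigma
        prev = self._ar_state
        for i, e in enumerate(eps):
            if prev is None:
                prev = s.sigma * e  # deviation from the mean
            else:
                prev = s.phi * prev + innov * e
            out[i] = s.mean + prev
        if eps.size:
            self._ar_state = prev
        return out


def make_sampler(spec: GeneratorSpec) -> SyntheticSampler:
    """Instantiate a fresh stream for ``spec`` (validates the spec)."""
    return SyntheticSampler(spec)


def stream_determinism_check(spec: GeneratorSpec, partitions: Iterable[Iterable[float]]) -> bool:
    """True iff every call partition of the same total duration yields
    the identical concatenated stream.

    ``partitions`` is an iterable of extend-call duration sequences;
    all must sum to the same total within one sample.
    """
    streams = []
    for part in partitions:
        sampler = make_sampler(spec)
        chunks = [sampler.extend(d) for d in part]
        streams.append(np.concatenate(chunks) if chunks else np.empty(0))
    first = streams[0]
    return all(s.size == first.size and np.array_equal(s, first) for s in streams[1:])
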