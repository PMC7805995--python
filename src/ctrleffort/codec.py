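"""Discretization of control signals and their information content.

A continuous control signal (a muscle stimulation, a joint torque command, or
a proprioceptive sensor reading) is reduced to ``n`` amplitude levels and
``m`` sample-and-hold updates over the movement.  The information such a
signal can carry is at most ``m * log2(n)`` bits (uniform symbol use); the
information it actually carries is ``m`` times the Shannon entropy of its
emitted symbol distribution.  The first quantity is the cheap cost function
of the control-effort optimization, the second is the reported control
effort ``I_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResolutionVector",
    "SignalSpec",
    "DiscretizedTrace",
    "SymbolHistogram",
    "quantize_amplitude",
    "discretize_trace",
    "info_uniform",
    "info_empirical",
    "bits_per_second",
    "read_signal_csv",
    "write_signal_csv",
]


@dataclass(frozen=True)
class ResolutionVector:
    """Amplitude/time resolution parameters ``(n_1, m_1, ..., n_N, m_N)``.

    One ``(n_i, m_i)`` pair per control signal: ``n_i`` amplitude levels and
    ``m_i`` sample-and-hold updates, both positive integers.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(n), int(m)) for n, m in self.pairs)
        for n, m in pairs:
            if n < 1 or m < 1:
                raise ValueError(
                    f"resolution entries must be >= 1, got (n={n}, m={m})"
                )
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def from_flat(cls, entries: Sequence[int]) -> "ResolutionVector":
        """Build from the flat ``(n_1, m_1, n_2, m_2, ...)`` layout."""
        if len(entries) % 2 != 0:
            raise ValueError("flat resolution vector must have even length")
        it = iter(entries)
        return cls(tuple(zip(it, it)))

    @property
    def n_signals(self) -> int:
        return len(self.pairs)

    def as_flat(self) -> tuple[int, ...]:
        return tuple(x for pair in self.pairs for x in pair)

    def __len__(self) -> int:
        return 2 * len(self.pairs)

    def __iter__(self):
        return iter(self.as_flat())


@dataclass(frozen=True)
class SignalSpec:
    """Metadata for one discretized signal.

    ``u_min == u_max`` is allowed for a constant signal and forces single-level
    (``n = 1``) semantics regardless of the requested amplitude resolution.
    """

    name: str
    u_min: float
    u_max: float
    T: float
    role: str = "controller-output"  # or "controller-input"

    def __post_init__(self) -> None:
        if self.u_min > self.u_max:
            raise ValueError(f"{self.name}: u_min must not exceed u_max")
        if not self.T > 0:
            raise ValueError(f"{self.name}: duration T must be positive")
        if self.role not in ("controller-output", "controller-input"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")


@dataclass
class DiscretizedTrace:
    """A signal after amplitude quantization and zero-order hold in time."""

    spec: SignalSpec
    n: int
    sample_times: np.ndarray  # shape (m,)
    symbols: np.ndarray       # shape (m,), integers in 1..n
    levels: np.ndarray        # shape (m,), quantized amplitude values

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.symbols = np.asarray(self.symbols, dtype=int)
        self.levels = np.asarray(self.levels, dtype=float)
        if not (self.sample_times.shape == self.symbols.shape == self.levels.shape):
            raise ValueError("sample_times, symbols and levels must align")
        if self.symbols.size and (self.symbols.min() < 1 or self.symbols.max() > self.n):
            raise ValueError("symbol index out of range 1..n")

    @property
    def m(self) -> int:
        return int(self.symbols.size)

    def value_at(self, t: float) -> float:
        """Zero-order-hold reconstruction: the level held at time ``t``."""
        k = int(np.searchsorted(self.sample_times, t, side="right")) - 1
        k = max(k, 0)
        return float(self.levels[k])

    def sampler(self) -> Callable[[float], float]:
        return self.value_at


@dataclass
class SymbolHistogram:
    """Symbol occupancy of one discretized signal."""

    counts: np.ndarray  # shape (n,), counts per symbol 1..n

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("symbol counts must be non-negative")

    @classmethod
    def from_trace(cls, trace: DiscretizedTrace) -> "SymbolHistogram":
        counts = np.bincount(trace.symbols, minlength=trace.n + 1)[1:]
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("histogram has no samples")
        return self.counts / self.total

    def entropy_bits(self) -> float:
        """Per-sample Shannon entropy ``-sum_j p_j log2 p_j`` (0 log 0 := 0)."""
        p = self.probabilities
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())


def quantize_amplitude(
    value: float, spec: SignalSpec, n: int
) -> tuple[int, float]:
    """Map ``value`` to the nearest of ``n`` uniform levels spanning the range.

    Levels include both endpoints: ``u_j = u_min + (j-1)(u_max-u_min)/(n-1)``
    for ``j = 1..n``; for ``n = 1`` the single level is the range midpoint.
    Values outside the range are clamped first.  Ties go to the larger level.
    Returns ``(symbol index, level value)``.
    """
    if not math.isfinite(value):
        raise ValueError(
            f"{spec.name}: non-finite signal value (corrupt simulation output)"
        )
    if n < 1:
        raise ValueError("amplitude level count n must be >= 1")
    lo, hi = spec.u_min, spec.u_max
    if n == 1 or hi == lo:
        return 1, 0.5 * (lo + hi)
    value = min(max(value, lo), hi)
    step = (hi - lo) / (n - 1)
    # floor(x + 0.5) rounds exact ties up, i.e. toward the larger level
    j0 = int(math.floor((value - lo) / step + 0.5))
    j0 = min(max(j0, 0), n - 1)
    return j0 + 1, lo + j0 * step


def discretize_trace(
    sampler: Callable[[float], float],
    spec: SignalSpec,
    n: int,
    m: int,
) -> DiscretizedTrace:
    """Sample ``sampler`` at ``t_k = (k-1) T/m`` and quantize each sample.

    The reconstruction holds each quantized level until the next sample time
    (zero-order hold over ``[t_k, t_{k+1})``, the last level to the end).
    """
    if m < 1:
        raise ValueError("sample count m must be >= 1")
    times = np.arange(m) * (spec.T / m)
    symbols = np.empty(m, dtype=int)
    levels = np.empty(m, dtype=float)
    for k, t in enumerate(times):
        symbols[k], levels[k] = quantize_amplitude(float(sampler(float(t))), spec, n)
    return DiscretizedTrace(spec=spec, n=n, sample_times=times,
                            symbols=symbols, levels=levels)


def info_uniform(r: ResolutionVector) -> float:
    """Maximal information ``sum_i m_i log2 n_i`` in bits.

    This assumes every amplitude level is used with equal probability; it is
    the cheap, monotone cost function of the control-effort optimization.
    """
    return float(sum(m * math.log2(n) for n, m in r.pairs))


def info_empirical(traces: Iterable[DiscretizedTrace]) -> float:
    """Actual information carried by recorded symbol sequences, in bits.

    ``sum_i m_i H_i`` with ``H_i`` the Shannon entropy of signal *i*'s symbol
    occupancy.  Never exceeds :func:`info_uniform` of the matching resolution
    vector; equality holds exactly for uniform occupancy.
    """
    total = 0.0
    for trace in traces:
        hist = SymbolHistogram.from_trace(trace)
        total += trace.m * hist.entropy_bits()
    return float(total)


def bits_per_second(info_bits: float, T: float) -> float:
    """Information rate ``I / T`` in bit/s over the movement duration."""
    if not T > 0:
        raise ValueError("duration T must be positive")
    return float(info_bits) / float(T)


def write_signal_csv(path, times: np.ndarray, signals: dict[str, np.ndarray]) -> None:
    """Write wide-format signal CSV: header ``time,<name>,...`` in seconds."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float)})
    for name, values in signals.items():
        df[name] = np.asarray(values, dtype=float)
    # 17 significant digits: binary64 round-trips exactly through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_signal_csv(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a wide-format signal CSV back into ``(times, {name: values})``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError("signal CSV must have a 'time' column")
    times = df["time"].to_numpy(dtype=float)
    signals = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"
    }
    return times, signals
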