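"""Delayed-phase pulse encoding.

Converts a set of eight normalized 5x5 feature maps into an 8-channel
biphasic stimulation pulse program. Each feature-map pixel fires with a
latency that decreases with its intensity (spike-timing transform), is
offset by a position-dependent delay so pixels within a receptive field
spread out in time, and is then snapped to the nearest peak of a shared
subthreshold membrane oscillation (SMO). Pulses landing on the same peak
slot are merged, which compresses the program and enforces the minimum
inter-pulse interval of one SMO period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EncodingConfig",
    "PulseProgram",
    "PulseMatrix",
    "spike_time",
    "position_delay",
    "smo_align",
    "smo_value",
    "encode",
    "to_binary_matrix",
    "from_binary_matrix",
    "sequence_distance",
]

#: delta such that arctan(delta * 1) == 1, making the latency transform
#: span exactly [0, t_max] on p in [0, 1].
DELTA_EXACT = math.tan(1.0)


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the delayed-phase encoder.

    Attributes
    ----------
    t_max:
        Maximum latency of the spike-timing transform (s). A pixel of
        value 0 fires at ``t_max``; a pixel of value 1 fires at
        ``t_max * (1 - arctan(delta))``.
    delta:
        Sharpness of the latency transform. The default ``tan(1)`` maps
        p=1 exactly to latency 0.
    n_rf:
        Pixels per receptive field (5 x 5 = 25).
    delay_scale:
        Span of the positional delay (s); pixel i is delayed by
        ``i / n_rf * delay_scale``.
    smo_amplitude, smo_period, smo_phase0:
        Cosine SMO ``A cos(2 pi t / T + phi0)``. Peaks at multiples of
        the period define the slot grid pulses snap to.
    window:
        Stimulation duration (s); the slot grid covers ``[0, window)``.
    min_interval:
        Minimum spacing between pulses on one channel (s). Guaranteed by
        construction because slots are one SMO period apart.
    pulse_amplitude_mv, phase_duration_us:
        Biphasic pulse shape metadata (not used numerically here).
    significance_floor:
        Pixels below this value emit no pulse; ``None`` disables the
        floor so every pixel emits.
    """

    t_max: float = 1.0
    delta: float = DELTA_EXACT
    n_rf: int = 25
    delay_scale: float = 1.0
    smo_amplitude: float = 1.0
    smo_period: float = 0.200
    smo_phase0: float = 0.0
    window: float = 2.0
    min_interval: float = 0.200
    pulse_amplitude_mv: float = 500.0
    phase_duration_us: float = 500.0
    significance_floor: float | None = 0.05

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_rf < 1:
            raise ValueError("n_rf must be >= 1")
        if self.smo_period < self.min_interval:
            raise ValueError(
                "smo_period must be >= min_interval: slots are the only "
                "admissible pulse times"
            )
        ratio = self.window / self.smo_period
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window must be an integer number of SMO periods")

    @property
    def n_slots(self) -> int:
        """Number of SMO peak slots in the stimulation window."""
        return int(round(self.window / self.smo_period))

    @property
    def slot_times(self) -> np.ndarray:
        """Peak times ``{k*T : k = 0..n_slots-1}`` (s)."""
        return np.arange(self.n_slots) * self.smo_period


@dataclass
class PulseProgram:
    """Per-channel pulse onset times for the 8 stimulation electrodes."""

    channels: list[np.ndarray]
    slot_period: float = 0.200
    window: float = 2.0
    pulse_amplitude_mv: float = 500.0
    phase_duration_us: float = 500.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) != 8:
            raise ValueError("a pulse program has exactly 8 channels")
        clean = []
        for times in self.channels:
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.window + 1e-9):
                raise ValueError("pulse times must lie in [0, window)")
            if t.size > 1:
                gaps = np.diff(t)
                if (gaps <= 0).any():
                    raise ValueError("pulse times must be strictly ascending")
                if (gaps < self.slot_period - 1e-9).any():
                    raise ValueError(
                        "within-channel pulse gap below the minimum interval"
                    )
            clean.append(t)
        self.channels = clean

    @property
    def n_pulses(self) -> int:
        return int(sum(t.size for t in self.channels))

    def all_pulses(self) -> list[tuple[int, float]]:
        """(electrode, onset time) pairs, time-sorted."""
        pairs = [
            (e, float(t)) for e, times in enumerate(self.channels) for t in times
        ]
        return sorted(pairs, key=lambda p: (p[1], p[0]))


@dataclass(frozen=True)
class PulseMatrix:
    """Binary slot-grid view of a pulse program (rows = channels)."""

    bits: np.ndarray
    slot_period: float = 0.200

    def __post_init__(self) -> None:
        b = np.asarray(self.bits)
        if b.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", b.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape


def spike_time(p, cfg: EncodingConfig = EncodingConfig()):
    """Latency of a pixel of normalized value ``p``.

    ``t = t_max * (1 - arctan(delta * p))``, clamped below at zero so a
    user-supplied ``delta > tan(1)`` cannot produce negative latencies.
    Strictly decreasing in p: stronger features fire earlier.
    """
    arr = np.asarray(p, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("pixel values must be finite")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("pixel values must lie in [0, 1]")
    t = cfg.t_max * (1.0 - np.arctan(cfg.delta * arr))
    t = np.maximum(t, 0.0)
    return float(t) if np.isscalar(p) else t


def position_delay(i, cfg: EncodingConfig = EncodingConfig()):
    """Positional delay of pixel index ``i`` (row-major within its RF)."""
    arr = np.asarray(i)
    if (arr < 0).any() or (arr >= cfg.n_rf).any():
        raise ValueError(f"pixel index must lie in [0, {cfg.n_rf})")
    d = arr / cfg.n_rf * cfg.delay_scale
    return float(d) if np.isscalar(i) else d


def smo_value(t, cfg: EncodingConfig = EncodingConfig()):
    """The SMO waveform ``A cos(omega t + phi0)`` with omega = 2 pi / T."""
    omega = 2.0 * math.pi / cfg.smo_period
    return cfg.smo_amplitude * np.cos(omega * np.asarray(t, float) + cfg.smo_phase0)


def smo_align(t, cfg: EncodingConfig = EncodingConfig()):
    """Snap time ``t`` to the nearest SMO peak slot; ties go earlier.

    Raw latencies can exceed the last peak (at ``window - T``); they are
    absorbed into that final slot, keeping the program inside the
    half-open stimulation window.
    """
    arr = np.asarray(t, dtype=float)
    if (arr < 0).any() or (arr > cfg.window + 1e-12).any():
        raise ValueError("time outside the stimulation window")
    T = cfg.smo_period
    k0 = np.floor(arr / T).astype(int)
    k0 = np.clip(k0, 0, cfg.n_slots - 1)
    k1 = np.clip(k0 + 1, 0, cfg.n_slots - 1)
    d0 = np.abs(arr - k0 * T)
    d1 = np.abs(arr - k1 * T)
    # strict inequality: equidistant times resolve to the earlier peak
    k = np.where(d1 < d0 - 1e-12, k1, k0)
    out = k * T
    return float(out) if np.isscalar(t) else out


def encode(feature_maps, cfg: EncodingConfig = EncodingConfig()) -> PulseProgram:
    """Encode eight 5x5 feature maps into an 8-channel pulse program.

    For each map (one receptive field per stimulation channel) every
    admitted pixel i with value p_i emits a raw time
    ``spike_time(p_i) + position_delay(i)``; raw times are snapped to
    the SMO peak grid and duplicates within a channel are merged.
    """
    maps = np.asarray(getattr(feature_maps, "maps", feature_maps), dtype=float)
    if maps.shape[0] != 8:
        raise ValueError("expected 8 feature maps")
    channels = []
    for m in maps:
        p = m.ravel()  # row-major pixel order
        if p.size != cfg.n_rf:
            raise ValueError(
                f"receptive field has {p.size} pixels, config says {cfg.n_rf}"
            )
        idx = np.arange(cfg.n_rf)
        if cfg.significance_floor is not None:
            keep = p >= cfg.significance_floor
            p, idx = p[keep], idx[keep]
        if p.size == 0:
            channels.append(np.empty(0))
            continue
        raw = spike_time(p, cfg) + position_delay(idx, cfg)
        aligned = smo_align(np.minimum(raw, cfg.window), cfg)
        channels.append(np.unique(aligned))
    return PulseProgram(
        channels=channels,
        slot_period=cfg.smo_period,
        window=cfg.window,
        pulse_amplitude_mv=cfg.pulse_amplitude_mv,
        phase_duration_us=cfg.phase_duration_us,
        provenance={"source": getattr(feature_maps, "source", None)},
    )


def to_binary_matrix(pp: PulseProgram) -> PulseMatrix:
    """Map a pulse program onto its binary channels-by-slots matrix."""
    n_slots = int(round(pp.window / pp.slot_period))
    bits = np.zeros((8, n_slots), dtype=np.int8)
    for c, times in enumerate(pp.channels):
        for t in times:
            k = int(round(t / pp.slot_period))
            if abs(t - k * pp.slot_period) > 1e-9 or not 0 <= k < n_slots:
                raise ValueError(f"pulse at {t} s is off the slot grid")
            bits[c, k] = 1
    return PulseMatrix(bits=bits, slot_period=pp.slot_period)


def from_binary_matrix(pm: PulseMatrix, window: float = 2.0) -> PulseProgram:
    """Inverse of :func:`to_binary_matrix`."""
    channels = [
        np.flatnonzero(row).astype(float) * pm.slot_period for row in pm.bits
    ]
    return PulseProgram(channels=channels, slot_period=pm.slot_period, window=window)


def sequence_distance(u: PulseMatrix | np.ndarray, v: PulseMatrix | np.ndarray) -> float:
    """Euclidean distance between two binary pulse matrices."""
    a = np.asarray(getattr(u, "bits", u), dtype=float)
    b = np.asarray(getattr(v, "bits", v), dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shapes")
    return float(np.sqrt(((a - b) ** 2).sum()))
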