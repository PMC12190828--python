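"""Synthetic cultured-network activity generator and spike detection.

The wet-lab side of the pipeline — a dissociated neuronal culture on a
high-density microelectrode array — is replaced here by a statistical
simulator reproducing the phenomenology the decoding and connectivity
analyses depend on:

* spontaneous activity: per-channel homogeneous Poisson background plus
  network-wide synchronized bursts;
* evoked activity: each stimulation pulse on electrode e adds, on every
  recording channel c, a Poisson number of extra spikes with mean
  ``gain[e, c]``, spread after a short conduction latency by an
  exponential decay kernel (tau = 50 ms) so the network returns to
  baseline well within 0.2 s of a pulse;
* slow plasticity: an optional per-stage multiplier on the evoked gain,
  emulating the gradual strengthening of stimulus-specific responses
  over repeated training.

The raw-signal path (Gaussian noise + stereotyped spike waveforms,
band-pass filtering and 5.5-sigma threshold detection) and the
amplitude-based electrode-selection rule are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .encoding import PulseProgram

__all__ = [
    "SpikeEventTable",
    "SimulatorConfig",
    "VoltageTrace",
    "make_gain",
    "simulate_spontaneous",
    "simulate_evoked",
    "simulate_session",
    "inject_correlated_pairs",
    "synthesize_voltage",
    "detect_spikes",
    "select_electrodes",
]


@dataclass
class SpikeEventTable:
    """Time-sorted (channel, time) spike events from one recording."""

    channels: np.ndarray
    times: np.ndarray
    n_channels: int = 1024
    duration: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.int64)
        t = np.asarray(self.times, dtype=float)
        if ch.shape != t.shape:
            raise ValueError("channels and times must have equal length")
        if t.size:
            if t.min() < 0 or t.max() > self.duration + 1e-9:
                raise ValueError("event times must lie in [0, duration]")
            if ch.min() < 0 or ch.max() >= self.n_channels:
                raise ValueError("channel ids must lie in [0, n_channels)")
            order = np.argsort(t, kind="stable")
            ch, t = ch[order], t[order]
        self.channels, self.times = ch, t

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def counts_per_channel(self) -> np.ndarray:
        return np.bincount(self.channels, minlength=self.n_channels)

    def train(self, channel: int) -> np.ndarray:
        """Sorted spike times for one channel."""
        return np.sort(self.times[self.channels == channel])


@dataclass(frozen=True)
class SimulatorConfig:
    """Statistical parameters of the synthetic network.

    ``gain[e, c]`` is the expected number of extra spikes on recording
    channel c produced by one pulse on stimulation electrode e.
    """

    n_channels: int = 1024
    spontaneous_rate: float = 0.5  # Hz per channel
    burst_rate_per_min: float = 6.0
    burst_participation: float = 0.3
    burst_boost_hz: float = 25.0
    burst_duration: float = 0.1  # s
    gain: np.ndarray | None = None  # (8, n_channels)
    decay_tau: float = 0.05  # s
    latency: float = 0.002  # s
    refractory: float = 0.002  # s
    plasticity_drift: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spontaneous_rate", "burst_rate_per_min", "burst_boost_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # evoked rate must fall below 5% of peak by 0.2 s post-pulse
        if self.decay_tau <= 0 or np.exp(-0.2 / self.decay_tau) >= 0.05:
            raise ValueError("decay_tau too slow: network must recover within 0.2 s")
        if self.gain is not None:
            g = np.asarray(self.gain, dtype=float)
            if g.ndim != 2 or g.shape[1] != self.n_channels:
                raise ValueError("gain must have shape (n_stim, n_channels)")
            if (g < 0).any():
                raise ValueError("gains must be >= 0")
            object.__setattr__(self, "gain", g)


@dataclass
class VoltageTrace:
    """Raw multichannel voltage (mV) sampled at ``fs`` Hz."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.isfinite(s).all():
            raise ValueError("voltage samples must be finite")
        if self.fs <= 6000:
            raise ValueError("sampling rate must exceed 6 kHz (3 kHz band edge)")
        self.samples = s


def make_gain(
    n_channels: int,
    n_stim: int = 8,
    seed: int = 0,
    base: float = 0.05,
    drive: float = 2.0,
    p_drive: float = 0.1,
    sigma: float = 0.5,
) -> np.ndarray:
    """Draw a structured stimulation-gain matrix.

    Each stimulation electrode strongly drives a random subset of
    channels (fraction ``p_drive``) with log-normal strengths around
    ``drive`` expected spikes per pulse, on top of a weak uniform
    coupling ``base``. Distinct pulse programs then evoke separable
    spatial activity patterns.
    """
    rng = np.random.default_rng(seed)
    strong = rng.random((n_stim, n_channels)) < p_drive
    ln = rng.lognormal(mean=np.log(max(drive, 1e-9)), sigma=sigma, size=(n_stim, n_channels))
    return base + strong * ln


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy removal of spikes closer than the refractory period."""
    if times.size < 2 or refractory <= 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def _spontaneous_events(duration, cfg, rng):
    """Background + burst events as (channels, times) arrays."""
    counts = rng.poisson(cfg.spontaneous_rate * duration, size=cfg.n_channels)
    ch = np.repeat(np.arange(cfg.n_channels), counts)
    t = rng.uniform(0.0, duration, size=counts.sum())
    chunks_ch, chunks_t = [ch], [t]
    n_bursts = rng.poisson(cfg.burst_rate_per_min * duration / 60.0)
    for _ in range(n_bursts):
        t0 = rng.uniform(0.0, duration)
        members = np.flatnonzero(rng.random(cfg.n_channels) < cfg.burst_participation)
        if members.size == 0:
            continue
        k = rng.poisson(cfg.burst_boost_hz * cfg.burst_duration, size=members.size)
        bch = np.repeat(members, k)
        bt = t0 + rng.uniform(0.0, cfg.burst_duration, size=k.sum())
        sel = bt <= duration
        chunks_ch.append(bch[sel])
        chunks_t.append(bt[sel])
    return np.concatenate(chunks_ch), np.concatenate(chunks_t)


def _finalize(ch, t, duration, cfg, metadata):
    """Sort per channel, apply the refractory period, build the table."""
    if ch.size:
        order = np.lexsort((t, ch))
        ch, t = ch[order], t[order]
        out_ch, out_t = [], []
        for c in np.unique(ch):
            block = t[np.searchsorted(ch, c) : np.searchsorted(ch, c, side="right")]
            kept = _thin_refractory(block, cfg.refractory)
            out_ch.append(np.full(kept.size, c))
            out_t.append(kept)
        ch = np.concatenate(out_ch)
        t = np.concatenate(out_t)
    return SpikeEventTable(
        channels=ch, times=t, n_channels=cfg.n_channels,
        duration=duration, metadata=metadata,
    )


def simulate_spontaneous(
    duration: float, cfg: SimulatorConfig, seed: int, metadata: dict | None = None
) -> SpikeEventTable:
    """Spontaneous recording: Poisson background + synchronized bursts."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    ch, t = _spontaneous_events(duration, cfg, rng)
    return _finalize(ch, t, duration, cfg, dict(metadata or {}, kind="spontaneous"))


def simulate_evoked(
    pp: PulseProgram,
    cfg: SimulatorConfig,
    seed: int,
    gain_multiplier: float = 1.0,
    metadata: dict | None = None,
) -> SpikeEventTable:
    """One evoked trial: spontaneous background + pulse-locked transients.

    The instantaneous evoked rate on channel c is
    ``sum_pulses gain[e, c]/tau * exp(-(t - t_p - latency)/tau)`` for
    ``t > t_p + latency``, so each pulse contributes ``gain[e, c]``
    expected spikes. Evoked spikes are superposed on the background
    without refractory thinning, preserving the Poisson mean.
    """
    if cfg.gain is None:
        raise ValueError("SimulatorConfig.gain must be set for evoked simulation")
    if cfg.gain.shape[0] != len(pp.channels):
        raise ValueError("gain rows must match the number of stimulation electrodes")
    duration = pp.window
    rng = np.random.default_rng(seed)
    ch, t = _spontaneous_events(duration, cfg, rng)
    base = _finalize(ch, t, duration, cfg, {})
    ev_ch, ev_t = [base.channels], [base.times]
    for e, t_p in pp.all_pulses():
        counts = rng.poisson(cfg.gain[e] * gain_multiplier)
        total = int(counts.sum())
        if total == 0:
            continue
        offs = rng.exponential(cfg.decay_tau, size=total)
        tt = t_p + cfg.latency + offs
        cc = np.repeat(np.arange(cfg.n_channels), counts)
        sel = tt <= duration
        ev_ch.append(cc[sel])
        ev_t.append(tt[sel])
    md = dict(metadata or {}, kind="evoked",
              stim_onsets=[float(tp) for _, tp in pp.all_pulses()])
    return SpikeEventTable(
        channels=np.concatenate(ev_ch), times=np.concatenate(ev_t),
        n_channels=cfg.n_channels, duration=duration, metadata=md,
    )


def _stage_of_trial(idx: int, stage_len: int = 15) -> int:
    """Training epoch of 1-based trial index: 1-15 -> 1, 16-30 -> 2, ..."""
    return (idx - 1) // stage_len + 1


def simulate_session(
    programs: Sequence[PulseProgram],
    cfg: SimulatorConfig,
    seed: int,
    n_trials: int = 50,
    stage_len: int = 15,
    n_test: int = 5,
    n_spontaneous: int = 50,
    spontaneous_duration: float = 2.0,
    blank: bool = False,
) -> list[SpikeEventTable]:
    """Full stimulation session: 9 programs x 50 trials + 50 spontaneous 2-s segments.

    Trials 1-15, 16-30 and 31-45 are the three training stages; the 5
    trials following each stage (16-20, 31-35, 46-50) are that stage's
    held-out test trials. The plasticity drift multiplies the evoked
    gain by ``drift**(epoch-1)`` where epoch is the trial's position in
    the staged schedule, emulating training-induced strengthening.
    With ``blank=True`` every table is empty (chip without neurons).
    """
    if len(programs) < 9:
        raise ValueError("the staged protocol requires 9 pulse programs")
    n_stages = (n_trials - n_test) // stage_len
    rng = np.random.default_rng(seed)
    tables: list[SpikeEventTable] = []
    for s, pp in enumerate(programs):
        for idx in range(1, n_trials + 1):
            epoch = _stage_of_trial(idx, stage_len)
            mult = cfg.plasticity_drift ** (epoch - 1)
            train_stage = epoch if idx <= n_stages * stage_len else None
            test_stage = None
            r = (idx - 1) % stage_len
            if idx > stage_len and r < n_test:
                test_stage = (idx - 1) // stage_len
            md = {
                "stimulus": s, "trial": idx,
                "train_stage": train_stage, "test_stage": test_stage,
            }
            if blank:
                tables.append(SpikeEventTable(
                    channels=np.empty(0, int), times=np.empty(0),
                    n_channels=cfg.n_channels, duration=pp.window,
                    metadata=dict(md, kind="evoked",
                                  stim_onsets=[t for _, t in pp.all_pulses()]),
                ))
            else:
                tables.append(simulate_evoked(
                    pp, cfg, int(rng.integers(2**31)), gain_multiplier=mult,
                    metadata=md,
                ))
    for idx in range(1, n_spontaneous + 1):
        epoch = _stage_of_trial(idx, stage_len)
        train_stage = epoch if idx <= n_stages * stage_len else None
        test_stage = None
        r = (idx - 1) % stage_len
        if idx > stage_len and r < n_test:
            test_stage = (idx - 1) // stage_len
        md = {"stimulus": None, "trial": idx,
              "train_stage": train_stage, "test_stage": test_stage}
        if blank:
            tables.append(SpikeEventTable(
                channels=np.empty(0, int), times=np.empty(0),
                n_channels=cfg.n_channels, duration=spontaneous_duration,
                metadata=dict(md, kind="spontaneous", stim_onsets=[]),
            ))
        else:
            tables.append(simulate_spontaneous(
                spontaneous_duration, cfg, int(rng.integers(2**31)), metadata=md
            ))
    return tables


def inject_correlated_pairs(
    table: SpikeEventTable,
    pairs: Sequence[tuple[int, int]],
    shared_rate: float,
    seed: int,
    jitter_sd: float = 0.003,
) -> SpikeEventTable:
    """Add shared (near-coincident) events to channel pairs.

    Used to synthesize 'after training' recordings in which specific
    channel pairs have become functionally coupled: each pair receives
    a common Poisson event stream at ``shared_rate`` Hz, realized on
    both channels with independent Gaussian timing jitter.
    """
    rng = np.random.default_rng(seed)
    ch = [table.channels]
    t = [table.times]
    for a, b in pairs:
        n = rng.poisson(shared_rate * table.duration)
        t0 = rng.uniform(0.0, table.duration, size=n)
        for c in (a, b):
            tt = np.clip(t0 + rng.normal(0.0, jitter_sd, size=n), 0, table.duration)
            ch.append(np.full(n, c))
            t.append(tt)
    return SpikeEventTable(
        channels=np.concatenate(ch), times=np.concatenate(t),
        n_channels=table.n_channels, duration=table.duration,
        metadata=dict(table.metadata, correlated_pairs=list(map(tuple, pairs))),
    )


# ---------------------------------------------------------------------------
# raw-voltage path: waveform synthesis and threshold spike detection
# ---------------------------------------------------------------------------

def _default_template(fs: float, amplitude: float) -> np.ndarray:
    """Stereotyped extracellular spike: sharp negative peak, slow positive rebound."""
    t = np.arange(int(1.6e-3 * fs)) / fs
    wave = -np.exp(-((t - 4e-4) ** 2) / (2 * (1.2e-4) ** 2))
    wave += 0.4 * np.exp(-((t - 9e-4) ** 2) / (2 * (2.5e-4) ** 2))
    return amplitude * wave


def synthesize_voltage(
    st: SpikeEventTable,
    fs: float = 20000.0,
    noise_sd: float = 0.01,
    spike_template: np.ndarray | None = None,
    template_amplitude: float = 0.12,
    seed: int = 0,
) -> VoltageTrace:
    """Render a spike table as raw voltage: Gaussian noise + inserted waveforms."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(st.duration * fs))
    v = rng.normal(0.0, noise_sd, size=(st.n_channels, n_samples))
    tpl = spike_template if spike_template is not None else _default_template(
        fs, template_amplitude
    )
    for c, t in zip(st.channels, st.times):
        i0 = int(round(t * fs))
        seg = tpl[: max(0, n_samples - i0)]
        v[c, i0 : i0 + seg.size] += seg
    return VoltageTrace(
        samples=v, fs=fs,
        metadata={"n_events": st.n_events, "noise_sd": noise_sd},
    )


def detect_spikes(
    v: VoltageTrace,
    band: tuple[float, float] = (300.0, 3000.0),
    threshold_sd: float = 5.5,
    refractory: float = 0.002,
) -> SpikeEventTable:
    """Band-pass + threshold spike detection on raw voltage.

    Zero-phase 4th-order Butterworth band-pass (300-3000 Hz); the noise
    sd is estimated robustly as ``median(|x|)/0.6745``; a spike is
    called where the filtered magnitude exceeds ``threshold_sd`` times
    that estimate, with one event (at the local extremum) per
    supra-threshold excursion and a per-channel refractory period.
    """
    sos = sps.butter(4, band, btype="bandpass", fs=v.fs, output="sos")
    padlen = 3 * 4 * 2  # conservative estimate of sosfiltfilt warm-up
    if v.samples.shape[1] <= 3 * padlen:
        raise ValueError("trace shorter than the filter warm-up")
    ch_out, t_out = [], []
    ref_n = int(round(refractory * v.fs))
    for c in range(v.samples.shape[0]):
        x = sps.sosfiltfilt(sos, v.samples[c])
        sd = np.median(np.abs(x)) / 0.6745
        if sd == 0:
            continue
        above = np.abs(x) > threshold_sd * sd
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
        if above[0]:
            edges = np.concatenate(([0], edges))
        last = -np.inf
        for i0 in edges:
            i1 = i0
            while i1 < above.size and above[i1]:
                i1 += 1
            peak = i0 + int(np.argmax(np.abs(x[i0:i1])))
            if peak - last >= ref_n:
                ch_out.append(c)
                t_out.append(peak / v.fs)
                last = peak
    return SpikeEventTable(
        channels=np.asarray(ch_out, int), times=np.asarray(t_out, float),
        n_channels=v.samples.shape[0], duration=v.samples.shape[1] / v.fs,
        metadata={"detector": f"butter4-{band[0]:g}-{band[1]:g}-{threshold_sd}sd"},
    )


def select_electrodes(
    amplitude_per_channel: np.ndarray, n_record: int = 1024, n_stim: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-ranked electrode selection.

    Recording electrodes are the ``n_record`` channels with the highest
    spike amplitudes; stimulation electrodes the top ``n_stim`` of
    those. Ties break toward the lower channel id.
    """
    amp = np.asarray(amplitude_per_channel, dtype=float)
    n = amp.size
    if n < n_record:
        warnings.warn(
            f"only {n} channels available for {n_record} recording electrodes; "
            "taking all", stacklevel=2,
        )
    order = np.lexsort((np.arange(n), -amp))
    rec = np.sort(order[: min(n_record, n)])
    rec_order = rec[np.lexsort((rec, -amp[rec]))]
    stim = np.sort(rec_order[: min(n_stim, rec.size)])
    return rec, stim
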