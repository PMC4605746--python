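"""LFP preprocessing: band-pass filtering, instantaneous phase, neighbor
averaging on a multielectrode grid, and spike-triggered averages.

The phase that feeds the GLM comes from a zero-phase (forward-backward)
Chebyshev type II band-pass (4-25 Hz default, 40 dB stopband) followed by
the Hilbert transform; zero-phase filtering is used because a causal filter
would delay the signal and bias estimated preferred phases.  Phase 0
corresponds to local maxima of the filtered trace (cosine convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import cheby2, hilbert, sosfiltfilt

from .basis import wrap_phase

__all__ = [
    "ElectrodeArrayLayout",
    "bandpass",
    "instantaneous_phase",
    "neighbor_average",
    "spike_triggered_average",
]


def bandpass(x: np.ndarray, fs: float, band=(4.0, 25.0), order: int = 4,
             stopband_db: float = 40.0) -> np.ndarray:
    """Zero-phase Chebyshev type II band-pass filter.

    `fs` is the sampling rate in Hz.  Applied forward-backward
    (sosfiltfilt) so the output has no phase distortion; effective stopband
    attenuation is therefore at least `stopband_db`.
    """
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < fs/2 = {nyq}")
    sos = cheby2(order, stopband_db, [lo / nyq, hi / nyq], btype="bandpass",
                 output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a narrowband signal via the analytic signal.

    Returns phases in [-pi, pi); phase 0 at local maxima of the input
    (cosine convention).
    """
    return wrap_phase(np.angle(hilbert(np.asarray(x, dtype=float), axis=-1)))


@dataclass
class ElectrodeArrayLayout:
    """Rectangular multielectrode grid with optional missing channels.

    channel_positions maps channel name -> (row, col); by default a
    rows x cols grid of channels named ch_0 .. ch_{rc-1} in row-major order.
    """

    rows: int
    cols: int
    channel_positions: dict = field(default_factory=dict)
    missing: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.channel_positions:
            self.channel_positions = {
                f"ch_{r * self.cols + c}": (r, c)
                for r in range(self.rows) for c in range(self.cols)
            }
        pos = list(self.channel_positions.values())
        if len(set(pos)) != len(pos):
            raise ValueError("electrode positions must be unique")
        self._by_pos = {p: ch for ch, p in self.channel_positions.items()}

    def neighbors(self, channel: str, adjacency: int = 8) -> list:
        """Present neighboring channels (8-adjacent by default; 4 optional).
        Never includes the queried channel."""
        if channel not in self.channel_positions:
            raise KeyError(f"unknown channel {channel!r}")
        if adjacency not in (4, 8):
            raise ValueError("adjacency must be 4 or 8")
        r, c = self.channel_positions[channel]
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if adjacency == 8:
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        out = []
        for dr, dc in steps:
            ch = self._by_pos.get((r + dr, c + dc))
            if ch is not None and ch not in self.missing:
                out.append(ch)
        return out


def neighbor_average(lfps: dict, layout: ElectrodeArrayLayout, channel: str,
                     adjacency: int = 8) -> np.ndarray:
    """Unweighted mean LFP over the channel's present neighbors.

    `lfps` maps channel name -> 1-D trace (or a DataFrame-like with channel
    columns).  Edge and corner channels use whatever neighbors exist; a
    channel with no available neighbor is an error.
    """
    nbrs = [ch for ch in layout.neighbors(channel, adjacency) if ch in lfps]
    if not nbrs:
        raise ValueError(f"channel {channel!r} has no available neighbors")
    return np.mean([np.asarray(lfps[ch], dtype=float) for ch in nbrs], axis=0)


def spike_triggered_average(spikes, lfp, fs: float,
                            window=(0.1, 0.1), trial_ids=None):
    """Mean LFP segment aligned to spike times.

    `lfp` is a dict trial_id -> trace (or a single trace used for every
    trial), sampled at `fs` Hz on the trial clock.  `window` = (pre, post)
    seconds.  Spikes whose window would be clipped are excluded and counted.
    Returns (lags_s, sta, n_used, n_clipped).
    """
    pre, post = window
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    segs = []
    n_clipped = 0
    items = spikes.trials.items() if trial_ids is None else \
        [(tid, spikes.trials[tid]) for tid in trial_ids]
    for tid, times in items:
        trace = np.asarray(lfp[tid] if isinstance(lfp, dict) else lfp,
                           dtype=float)
        centers = np.round(times * fs).astype(int)
        for c in centers:
            if c - n_pre < 0 or c + n_post + 1 > len(trace):
                n_clipped += 1
                continue
            segs.append(trace[c - n_pre: c + n_post + 1])
    if not segs:
        raise ValueError("all spike-triggered windows were clipped")
    lags = np.arange(-n_pre, n_post + 1) / fs
    return lags, np.mean(segs, axis=0), len(segs), n_clipped
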