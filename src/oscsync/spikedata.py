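"""Data model and I/O for trial-structured spike trains and covariates.

Spike trains are kept as lists of per-trial spike-time arrays on a common
trial clock (seconds, 0-based within each trial).  Covariates (stimulus clock,
oscillation phase, optionally raw LFP) live on a uniform grid whose spacing
equals the model bin width.  `bin_spikes` turns both into the binned design
used by the GLM likelihood: 0/1 spike counts per bin, the lag since the most
recent spike, and the phase at each bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import wrap_phase

__all__ = [
    "SpikeTrainSet",
    "CovariateSeries",
    "BinnedDesign",
    "read_spike_trains",
    "write_spike_trains",
    "read_phase_series",
    "write_phase_series",
    "read_lfp",
    "bin_spikes",
]


@dataclass
class SpikeTrainSet:
    """Trial-structured spike times for one neuron.

    trials maps trial labels to strictly increasing spike-time arrays, all in
    (0, trial_length] seconds.
    """

    neuron_id: str
    trials: dict
    trial_length: float

    def __post_init__(self) -> None:
        clean = {}
        for tid, times in self.trials.items():
            t = np.asarray(times, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(
                    f"neuron {self.neuron_id}, trial {tid}: spike times not "
                    "strictly increasing"
                )
            if t.size and (t[0] <= 0 or t[-1] > self.trial_length):
                raise ValueError(
                    f"neuron {self.neuron_id}, trial {tid}: spike times must "
                    f"lie in (0, {self.trial_length}]"
                )
            clean[tid] = t
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials.values()))

    def trial_ids(self) -> list:
        return list(self.trials.keys())

    def mean_rate(self) -> float:
        """Mean firing rate in Hz over all trials."""
        return self.n_spikes / (self.n_trials * self.trial_length)


@dataclass
class CovariateSeries:
    """Per-trial covariates on a uniform time grid (spacing = bin width)."""

    trial_id: object
    sample_times: np.ndarray
    phase: np.ndarray | None = None
    stimulus_clock: np.ndarray | None = None
    lfp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        dt = np.diff(self.sample_times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError(f"trial {self.trial_id}: sample grid not uniform")
        if self.phase is not None:
            self.phase = wrap_phase(np.asarray(self.phase, dtype=float))
            if self.phase.shape != self.sample_times.shape:
                raise ValueError(f"trial {self.trial_id}: phase length mismatch")
        if self.stimulus_clock is None:
            self.stimulus_clock = self.sample_times

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])


@dataclass
class BinnedDesign:
    """Binned representation of one neuron's spikes + covariates.

    counts, last_spike_lag and phase_per_bin are (n_trials, K) arrays;
    has_history marks bins at/after each trial's first spike (the auto-history
    term is inactive before it).  Bin k covers [k*dt, (k+1)*dt) and is indexed
    by its left edge; a spike on a boundary belongs to the later bin.
    """

    bin_width: float
    trial_ids: list
    counts: np.ndarray
    last_spike_lag: np.ndarray
    phase_per_bin: np.ndarray | None
    has_history: np.ndarray
    trial_length: float

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_times(self) -> np.ndarray:
        """Canonical per-bin evaluation times t_k (left edges)."""
        return np.arange(self.n_bins) * self.bin_width

    def total_spikes(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# I/O (CSV/TSV, header row; the same dialect is written and read back)
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spike_trains(path, trial_length: float,
                      trial_manifest=None) -> dict:
    """Read spike trains from delimited text into SpikeTrainSets per neuron.

    Expected columns: trial_id, neuron_id, spike_time_s.  Returns a dict
    neuron_id -> SpikeTrainSet.  `trial_manifest`, if given, is the full list
    of trial ids so that trials with zero spikes are retained.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = {"trial_id", "neuron_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = df.index[(df["spike_time_s"] <= 0) | (df["spike_time_s"] > trial_length)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{path}: row {row} has spike_time_s={df.loc[row, 'spike_time_s']} "
            f"outside (0, {trial_length}]"
        )
    out = {}
    for nid, g in df.groupby("neuron_id", sort=True):
        trials = {}
        for tid, gg in g.groupby("trial_id", sort=True):
            times = gg["spike_time_s"].to_numpy(dtype=float)
            if np.any(np.diff(times) <= 0):
                k = int(np.flatnonzero(np.diff(times) <= 0)[0])
                row = int(gg.index[k + 1])
                raise ValueError(
                    f"{path}: row {row}: non-monotone spike times in trial {tid}"
                )
            trials[tid] = times
        if trial_manifest is not None:
            for tid in trial_manifest:
                trials.setdefault(tid, np.empty(0))
            trials = {tid: trials[tid] for tid in trial_manifest}
        out[nid] = SpikeTrainSet(str(nid), trials, trial_length)
    return out


def write_spike_trains(path, spike_sets) -> None:
    """Write one or more SpikeTrainSets to delimited text (full precision)."""
    if isinstance(spike_sets, SpikeTrainSet):
        spike_sets = [spike_sets]
    rows = []
    for sts in spike_sets:
        for tid, times in sts.trials.items():
            for t in times:
                rows.append((tid, sts.neuron_id, repr(float(t))))
    df = pd.DataFrame(rows, columns=["trial_id", "neuron_id", "spike_time_s"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_phase_series(path, covariates: list) -> None:
    """Write per-trial phase series as columns time_s, trial_id, phase."""
    frames = []
    for cov in covariates:
        frames.append(pd.DataFrame({
            "trial_id": cov.trial_id,
            "time_s": cov.sample_times,
            "phase": cov.phase,
        }))
    pd.concat(frames).to_csv(path, sep=_sep_for(path), index=False)


def read_phase_series(path) -> list:
    """Read per-trial phase series written by `write_phase_series`."""
    df = pd.read_csv(path, sep=_sep_for(path))
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        out.append(CovariateSeries(tid, g["time_s"].to_numpy(),
                                   phase=g["phase"].to_numpy()))
    return out


def read_lfp(path) -> pd.DataFrame:
    """Read an LFP table with columns time_s, ch_<n>..."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a time_s column")
    return df


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_spikes(spikes: SpikeTrainSet, covariates=None,
               bin_width: float = 1e-3) -> BinnedDesign:
    """Bin a spike train set at width `bin_width` (default 1 ms).

    Covariates, when given, must be a dict trial_id -> CovariateSeries (or a
    list in trial order) on a grid matching the bin width.  Raises if any bin
    would hold two spikes — choose a smaller bin width in that case.
    """
    T = spikes.trial_length
    K = int(round(T / bin_width))
    if abs(K * bin_width - T) > 1e-9:
        raise ValueError("trial_length must be an integer number of bins")
    tids = spikes.trial_ids()
    n = len(tids)
    counts = np.zeros((n, K), dtype=np.int8)
    lags = np.zeros((n, K), dtype=float)
    has_hist = np.zeros((n, K), dtype=bool)
    phases = None

    if covariates is not None:
        if isinstance(covariates, dict):
            cov_map = covariates
        else:
            cov_map = {c.trial_id: c for c in covariates}
        phases = np.zeros((n, K), dtype=float)

    for i, tid in enumerate(tids):
        times = spikes.trials[tid]
        # spike at exactly t falls in bin floor(t / dt); boundary -> later bin
        idx = np.floor(times / bin_width + 1e-9).astype(int)
        idx = np.clip(idx, 0, K - 1)
        uniq, cnt = np.unique(idx, return_counts=True)
        if np.any(cnt > 1):
            b = int(uniq[cnt > 1][0])
            raise ValueError(
                f"trial {tid}: two spikes fall in bin {b} "
                f"([{b * bin_width:g}, {(b + 1) * bin_width:g}) s); "
                "use a smaller bin width"
            )
        counts[i, uniq] = 1
        # lag at bin k = t_k - most recent spike strictly before bin k
        if uniq.size:
            last = np.full(K, -1, dtype=int)
            marker = np.zeros(K, dtype=int)
            marker[uniq] = 1
            cum = np.cumsum(marker)
            spike_bin_of = np.concatenate([[-1], uniq])
            prev_idx = spike_bin_of[np.concatenate([[0], cum[:-1]])]
            valid = prev_idx >= 0
            has_hist[i, valid] = True
            edges = np.arange(K) * bin_width
            prev_times = np.where(valid, times[np.searchsorted(uniq, np.maximum(prev_idx, 0))], 0.0)
            lags[i, valid] = edges[valid] - prev_times[valid]
        if phases is not None:
            cov = cov_map[tid]
            if abs(cov.dt - bin_width) > 1e-9:
                raise ValueError(
                    f"trial {tid}: covariate grid spacing {cov.dt} does not "
                    f"match bin width {bin_width}"
                )
            if len(cov.phase) != K:
                raise ValueError(f"trial {tid}: phase series length != {K}")
            phases[i] = cov.phase

    assert int(counts.sum()) == spikes.n_spikes
    return BinnedDesign(bin_width, tids, counts, lags, phases, has_hist, T)
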