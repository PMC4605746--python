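"""Compiled inner loops for discrete-time spike-train generation.

The per-bin Bernoulli generation is inherently sequential in time (the hazard
depends on the most recent spike), so the hot loop is JIT-compiled with
numba.  All randomness enters through a pre-drawn array of uniforms, keeping
seeding explicit and outside the compiled code.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(nogil=True)
def simulate_bins(base_log, log_hist, dt, uniforms):
    """Sequential per-bin Bernoulli spike generation.

    base_log : (n_trials, K) log of the history-free intensity
               lambda1(t_k) * lambda3(phi_k) in Hz at each bin.
    log_hist : (L,) log auto-history multiplier for integer lag bins
               j = 1..L (lag (j - 0.5)*dt); lags beyond L use log_hist[-1]
               (constant extrapolation).  Pass zeros(1) for no history term.
    dt       : bin width in seconds.
    uniforms : (n_trials, K) iid U(0,1) draws.

    Returns (counts, intensity): int8 spike indicators and the per-bin
    conditional intensity (Hz) actually used, including history.
    """
    n, K = base_log.shape
    L = log_hist.shape[0]
    counts = np.zeros((n, K), dtype=np.int8)
    lam = np.empty((n, K))
    for i in range(n):
        last = -1
        for k in range(K):
            ll = base_log[i, k]
            if last >= 0:
                j = k - last
                if j > L:
                    j = L
                ll += log_hist[j - 1]
            v = np.exp(ll)
            lam[i, k] = v
            if uniforms[i, k] < v * dt:
                counts[i, k] = 1
                last = k
    return counts, lam
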