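"""Compiled inner loops for pair-lag binning.

Cross-correlogram counts are a two-pointer merge over two sorted spike-time
arrays: for every reference spike, target spikes within the lag window are
binned at half-open bin edges.  The batch variant runs one pass over many
surrogate train pairs concatenated with a spacing offset larger than the lag
window, so cross-surrogate lags can never land inside a bin.
"""

import numba
import numpy as np


@numba.njit(cache=False, fastmath=True)
def xcorr_counts(ref, tgt, half_window, bin_width, nbins):
    """Counts of (target - ref) lags in ``nbins`` half-open bins on
    ``[-half_window, +half_window)``."""
    out = np.zeros(nbins, dtype=np.int64)
    inv = 1.0 / bin_width
    j0 = 0
    n_tgt = tgt.size
    for i in range(ref.size):
        t = ref[i]
        lo = t - half_window
        while j0 < n_tgt and tgt[j0] < lo:
            j0 += 1
        j = j0
        while j < n_tgt:
            lag = tgt[j] - t
            if lag >= half_window:
                break
            b = int((lag + half_window) * inv)
            if b < nbins:
                out[b] += 1
            j += 1
    return out


@numba.njit(cache=False, fastmath=True)
def xcorr_counts_batch(ref, spacing, tgt, half_window, bin_width, nbins,
                       n_seg):
    """Per-segment correlogram counts over concatenated surrogate trains.

    ``ref`` and ``tgt`` are globally sorted concatenations in which segment
    ``s`` was shifted by ``s * spacing`` with ``spacing`` exceeding the
    recording span plus the lag window, so the segment of a spike is
    recoverable as ``t // spacing`` and cross-segment lags never fall
    inside the window.
    """
    out = np.zeros((n_seg, nbins), dtype=np.int64)
    inv = 1.0 / bin_width
    inv_sp = 1.0 / spacing
    j0 = 0
    n_tgt = tgt.size
    for i in range(ref.size):
        t = ref[i]
        s = int(t * inv_sp)
        if s >= n_seg:
            s = n_seg - 1
        lo = t - half_window
        while j0 < n_tgt and tgt[j0] < lo:
            j0 += 1
        j = j0
        while j < n_tgt:
            lag = tgt[j] - t
            if lag >= half_window:
                break
            b = int((lag + half_window) * inv)
            if b < nbins:
                out[s, b] += 1
            j += 1
    return out
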