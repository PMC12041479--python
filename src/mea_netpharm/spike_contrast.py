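"""Spike-Contrast: multivariate spike-train synchrony with adaptive time scale.

The measure scans bin sizes ``dt`` from half the recording duration down to a
minimum, shrinking geometrically.  For each ``dt`` the trains are counted into
half-overlapping bins (step ``dt/2``); with ``theta_k`` the total spike count
of all trains in bin ``k`` and ``n_k`` the number of trains active in bin
``k``:

* ``Contrast(dt)`` measures how strongly the population count fluctuates from
  bin to bin, normalized by twice the total spike count so that isolated
  synchronous events score 1 (each spike appears in two overlapping bins, so
  the overlapped bin sum already equals twice the spike count);
* ``ActiveST(dt) = (<n>_theta - 1) / (N - 1)`` is the spike-weighted fraction
  of simultaneously active trains, rescaled so one active train maps to 0 and
  all N trains to 1.

Synchrony at each scale is the product of the two, and the reported value is
the maximum over scales -- the time scale is selected by the data.  The
result lies in [0, 1]: 1 for identical trains, near 1/N for independent
Poisson trains at their best scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spike_io import SpikeTrainSet

logger = logging.getLogger(__name__)


@dataclass
class SyncCurve:
    """Synchrony curve over the scanned bin sizes (all in [0, 1])."""

    bin_sizes_s: np.ndarray
    contrast: np.ndarray
    active_st: np.ndarray

    @property
    def s(self) -> np.ndarray:
        return self.contrast * self.active_st

    @property
    def s_max(self) -> float:
        return float(self.s.max()) if self.s.size else 0.0

    @property
    def argmax_bin_s(self) -> float:
        return float(self.bin_sizes_s[int(np.argmax(self.s))]) if self.s.size else np.nan


def _bin_size_grid(t_max: float, min_bin_s: float, shrink: float) -> np.ndarray:
    sizes = []
    dt = t_max
    while dt >= min_bin_s:
        sizes.append(dt)
        dt *= shrink
    if not sizes:
        sizes = [min_bin_s]
    return np.asarray(sizes)


def spike_contrast(
    trains: SpikeTrainSet | list[np.ndarray],
    min_bin_s: float = 0.01,
    shrink: float = 0.9,
    max_bin_s: float | None = None,
    duration_s: float | None = None,
) -> tuple[float, SyncCurve]:
    """Spike-Contrast synchrony of a set of spike trains.

    Parameters
    ----------
    trains
        A :class:`~mea_netpharm.spike_io.SpikeTrainSet` or a list of
        spike-time arrays (seconds).  Empty trains are ignored.
    min_bin_s, shrink, max_bin_s
        Bin-size scan: geometric grid from ``max_bin_s`` (default: half the
        duration) shrinking by ``shrink`` down to ``min_bin_s``.
    duration_s
        Recording duration; taken from the SpikeTrainSet or the last spike.

    Returns
    -------
    (s_max, curve)
        The synchrony value (max of the curve) and the full curve.
    """
    if not 0 < shrink < 1:
        raise ValueError("shrink must be in (0, 1)")
    if isinstance(trains, SpikeTrainSet):
        duration_s = trains.duration_s if duration_s is None else duration_s
        arrs = [np.asarray(t, float) for t in trains.trains]
    else:
        arrs = [np.asarray(t, float) for t in trains]
    arrs = [t for t in arrs if t.size > 0]
    n_trains = len(arrs)
    total_spikes = sum(t.size for t in arrs)
    if n_trains < 2 or total_spikes < 2:
        logger.warning(
            "spike_contrast undefined (%d active trains, %d spikes); returning 0",
            n_trains,
            total_spikes,
        )
        empty = np.array([])
        return 0.0, SyncCurve(empty, empty, empty)
    if duration_s is None:
        duration_s = float(max(t[-1] for t in arrs))
    T = float(duration_s)
    if T <= 0:
        raise ValueError("duration must be positive")

    t_start = max_bin_s if max_bin_s is not None else T / 2.0
    bin_sizes = _bin_size_grid(t_start, min_bin_s, shrink)

    all_times = np.concatenate(arrs)
    train_ids = np.concatenate(
        [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(arrs)]
    )

    contrast = np.zeros(bin_sizes.size)
    active = np.zeros(bin_sizes.size)
    for s_idx, dt in enumerate(bin_sizes):
        step = dt / 2.0
        n_half = int(np.floor(T / step + 1e-9))
        n_bins = n_half - 1  # overlapped bins, each spanning two half-bins
        if n_bins < 1:
            continue
        half_idx = np.floor(all_times / step + 1e-12).astype(np.int64)
        keep = half_idx < n_half
        hi = half_idx[keep]
        ti = train_ids[keep]
        counts = np.bincount(ti * n_half + hi, minlength=n_trains * n_half)
        counts = counts.reshape(n_trains, n_half)
        per_train = counts[:, :-1] + counts[:, 1:]  # half-overlapping bins
        theta = per_train.sum(axis=0)
        theta_sum = theta.sum()
        if theta_sum == 0:
            continue
        n_k = (per_train > 0).sum(axis=0)
        # denominator 2 * (single-counted spikes) == overlapped bin sum
        contrast[s_idx] = min(np.abs(np.diff(theta)).sum() / theta_sum, 1.0)
        mean_active = (n_k * theta).sum() / theta_sum
        active[s_idx] = min(max((mean_active - 1.0) / (n_trains - 1), 0.0), 1.0)

    curve = SyncCurve(bin_sizes, contrast, active)
    return curve.s_max, curve
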