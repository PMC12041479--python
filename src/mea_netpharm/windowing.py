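"""Sliding-window segmentation and binary binning.

Recordings are cut into fixed-size windows (the data-augmentation step: 600 s
recordings yield e.g. 7 windows of 240 s at 75 % overlap), and each window is
converted to an electrodes x time-bins binary occupancy matrix.  All
intervals are half-open ``[start, end)``: a spike exactly at a window or bin
boundary belongs to the next unit, so nothing is double counted.  Trailing
samples that do not fill a whole window/bin are dropped, keeping all units
identically sized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_io import SpikeTrainSet

#: relative tolerance guarding floor() against floating-point boundary error
_EPS = 1e-9

DEFAULT_WINDOWS_S = (60.0, 120.0, 240.0)
DEFAULT_OVERLAPS_PCT = (0.0, 25.0, 50.0, 75.0)
DEFAULT_BINS_S = (0.001, 0.01, 0.1)


@dataclass(frozen=True)
class WindowSpec:
    """Window length and consecutive-window overlap (percent of window)."""

    window_s: float
    overlap_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap_pct < 100:
            raise ValueError("overlap_pct must be in [0, 100)")

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap_pct / 100.0)


def n_windows(duration_s: float, spec: WindowSpec) -> int:
    """Number of fully contained windows: floor((duration-window)/step) + 1."""
    if spec.window_s > duration_s:
        return 0
    return int(np.floor((duration_s - spec.window_s) / spec.step_s + _EPS)) + 1


def segment(sts: SpikeTrainSet, spec: WindowSpec) -> list[SpikeTrainSet]:
    """Cut a recording into sliding windows with times re-referenced to 0.

    Window ``k`` covers ``[k*step, k*step + window)``; only fully contained
    windows are emitted.  Each window carries ``(chip_id, condition,
    window_index)`` for grouped cross-validation downstream.
    """
    if spec.window_s > sts.duration_s:
        raise ValueError(
            f"window_s={spec.window_s} exceeds recording duration {sts.duration_s}"
        )
    windows = []
    for k in range(n_windows(sts.duration_s, spec)):
        t0 = k * spec.step_s
        t1 = t0 + spec.window_s
        trains = []
        for t in sts.trains:
            sel = t[(t >= t0) & (t < t1)] - t0
            # re-referencing can leave a value microscopically >= window_s
            trains.append(np.minimum(sel, np.nextafter(spec.window_s, 0.0)))
        windows.append(
            SpikeTrainSet(
                sts.chip_id,
                sts.condition,
                spec.window_s,
                trains,
                sts.excluded_electrodes,
                window_index=k,
                window_origin_s=t0,
            )
        )
    return windows


@dataclass
class BinnedMatrix:
    """Electrodes x time-bins binary occupancy of one window."""

    values: np.ndarray  # uint8, entries in {0, 1}
    bin_s: float
    window_origin_s: float = 0.0
    electrode_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (electrodes x bins)")
        if np.any(self.values > 1):
            raise ValueError("entries must be 0/1")
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.values.shape[0])
        else:
            self.electrode_ids = np.asarray(self.electrode_ids, dtype=int)

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_binary(window: SpikeTrainSet, bin_s: float) -> BinnedMatrix:
    """Binary-bin a window: entry 1 iff the electrode spiked in the bin.

    Bin ``j`` spans ``[j*bin_s, (j+1)*bin_s)``; the trailing partial bin is
    discarded.
    """
    if not bin_s > 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.floor(window.duration_s / bin_s + _EPS))
    values = np.zeros((window.n_electrodes, n_bins), dtype=np.uint8)
    for e, t in enumerate(window.trains):
        if t.size:
            idx = np.floor(t / bin_s + _EPS).astype(int)
            idx = idx[idx < n_bins]
            values[e, idx] = 1
    return BinnedMatrix(values, bin_s, window.window_origin_s)
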