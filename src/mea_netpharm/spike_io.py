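"""Spike-train containers, table I/O, and threshold-based spike detection.

The on-disk interchange format is a plain CSV with header
``chip_id,condition,electrode,time_s`` (one spike per row, '.' decimal,
times in seconds).  A leading ``#``-comment line carries recording metadata
(duration, electrode count, manually excluded electrodes) so that a
:class:`SpikeTrainSet` round-trips losslessly.

Raw voltage traces (for spike detection) are exchanged as HDF5 files with one
1-D dataset per electrode and a ``sampling_rate_hz`` attribute.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRE_DRUG = "pre_drug"
POST_DRUG = "post_drug"
CONDITIONS = (PRE_DRUG, POST_DRUG)

#: accepted spellings in input tables (the study labels conditions BIC00/BIC10)
_CONDITION_ALIASES = {
    "pre": PRE_DRUG,
    "pre_drug": PRE_DRUG,
    "bic00": PRE_DRUG,
    "control": PRE_DRUG,
    "post": POST_DRUG,
    "post_drug": POST_DRUG,
    "bic10": POST_DRUG,
    "drug": POST_DRUG,
}


def canonical_condition(name: str) -> str:
    key = str(name).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise ValueError(
            f"unknown condition {name!r}; expected one of {sorted(_CONDITION_ALIASES)}"
        )
    return _CONDITION_ALIASES[key]


@dataclass
class SpikeTrainSet:
    """One chip x condition recording: per-electrode sorted spike times.

    Parameters
    ----------
    chip_id
        Identifier of the MEA chip.
    condition
        ``"pre_drug"`` or ``"post_drug"``.
    duration_s
        Recording duration in seconds; every spike time lies in
        ``[0, duration_s]``.
    trains
        One float array of spike times per electrode (0-based index).
        Electrodes without activity have empty arrays.
    excluded_electrodes
        Indices manually excluded from analysis (noisy electrodes).
    window_index, window_origin_s
        Set by :func:`~mea_netpharm.windowing.segment` when the set is a
        window cut from a longer recording; ``None``/``0.0`` for full
        recordings.
    """

    chip_id: str
    condition: str
    duration_s: float
    trains: list[np.ndarray]
    excluded_electrodes: frozenset[int] = field(default_factory=frozenset)
    window_index: int | None = None
    window_origin_s: float = 0.0

    def __post_init__(self) -> None:
        self.condition = canonical_condition(self.condition)
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        self.excluded_electrodes = frozenset(int(i) for i in self.excluded_electrodes)
        for i, t in enumerate(self.trains):
            if t.ndim != 1:
                raise ValueError(f"electrode {i}: train must be 1-D")
            if t.size:
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"electrode {i}: spike times not sorted")
                if t[0] < 0 or t[-1] > self.duration_s:
                    raise ValueError(
                        f"electrode {i}: spike times outside [0, {self.duration_s}]"
                    )

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def spike_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains], dtype=int)

    def replace(self, **kwargs) -> "SpikeTrainSet":
        return replace(self, **kwargs)


@dataclass
class RawTrace:
    """Raw sampled voltage trace of one electrode (arbitrary units)."""

    electrode_id: int
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")


# ---------------------------------------------------------------------------
# spike-table CSV
# ---------------------------------------------------------------------------

_META_RE = re.compile(
    r"#\s*duration_s=(?P<dur>[^ ]+)\s+n_electrodes=(?P<n>\d+)(?:\s+excluded=(?P<exc>[\d,]*))?"
)


def write_spike_table(sts: SpikeTrainSet, path: str | Path) -> Path:
    """Write one recording in the spike-table CSV dialect (lossless)."""
    path = Path(path)
    excluded = ",".join(str(i) for i in sorted(sts.excluded_electrodes))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# duration_s={sts.duration_s!r} n_electrodes={sts.n_electrodes}"
            f" excluded={excluded}\n"
        )
        fh.write("chip_id,condition,electrode,time_s\n")
        for e, train in enumerate(sts.trains):
            for t in train:
                fh.write(f"{sts.chip_id},{sts.condition},{e},{float(t)!r}\n")
    return path


def read_spike_table(
    path: str | Path,
    duration_s: float | None = None,
    n_electrodes: int | None = None,
) -> SpikeTrainSet:
    """Read a spike-table CSV containing exactly one (chip, condition).

    ``duration_s``/``n_electrodes`` override or substitute the metadata
    comment line; without either source the duration defaults to the last
    spike time and the electrode count to the largest index seen.
    Malformed rows are rejected with the 1-based file line number.
    """
    sets = read_spike_tables(path, duration_s=duration_s, n_electrodes=n_electrodes)
    if len(sets) != 1:
        raise ValueError(
            f"{path}: expected a single (chip, condition) recording, found {len(sets)}"
        )
    return sets[0]


def read_spike_tables(
    path: str | Path,
    duration_s: float | None = None,
    n_electrodes: int | None = None,
) -> list[SpikeTrainSet]:
    """Read a spike-table CSV, returning one set per (chip, condition)."""
    path = Path(path)
    meta_dur = meta_n = None
    meta_exc: frozenset[int] = frozenset()
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = _META_RE.match(first.strip())
        if m:
            meta_dur = float(m.group("dur"))
            meta_n = int(m.group("n"))
            if m.group("exc"):
                meta_exc = frozenset(int(x) for x in m.group("exc").split(","))

    df = pd.read_csv(
        path, comment="#", dtype=str, skip_blank_lines=True,
        float_precision="round_trip",
    )
    expected = ["chip_id", "condition", "electrode", "time_s"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    # first data row is file line 3 when a metadata comment is present, else 2
    offset = 3 if first.startswith("#") else 2

    if len(df):
        electrode = pd.to_numeric(df["electrode"], errors="coerce")
        time_s = pd.to_numeric(df["time_s"], errors="coerce")
        bad = electrode.isna() | time_s.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise ValueError(f"{path}: malformed row at line {row + offset}")
        if (time_s < 0).any():
            row = int(np.flatnonzero((time_s < 0).values)[0])
            raise ValueError(f"{path}: negative spike time at line {row + offset}")
        # exact float round-trip: re-parse with Python's float()
        df = df.assign(
            electrode=electrode.astype(int), time_s=df["time_s"].map(float)
        )

    dur = duration_s if duration_s is not None else meta_dur
    n_el = n_electrodes if n_electrodes is not None else meta_n

    out: list[SpikeTrainSet] = []
    if len(df) == 0:
        if dur is None or n_el is None:
            raise ValueError(
                f"{path}: empty table without duration/electrode metadata"
            )
        return [
            SpikeTrainSet("unknown", PRE_DRUG, dur, [np.array([])] * n_el, meta_exc)
        ]

    file_dur = dur if dur is not None else float(df["time_s"].max())
    file_n = n_el if n_el is not None else int(df["electrode"].max()) + 1
    if (df["time_s"] > file_dur).any():
        row = int(np.flatnonzero((df["time_s"] > file_dur).values)[0])
        raise ValueError(
            f"{path}: spike time exceeds duration {file_dur} at line {row + offset}"
        )
    if (df["electrode"] >= file_n).any():
        row = int(np.flatnonzero((df["electrode"] >= file_n).values)[0])
        raise ValueError(f"{path}: electrode index out of range at line {row + offset}")

    for (chip, cond), grp in df.groupby(["chip_id", "condition"], sort=False):
        trains = [np.array([], dtype=float) for _ in range(file_n)]
        for e, sub in grp.groupby("electrode", sort=True):
            t = sub["time_s"].to_numpy()
            if np.any(np.diff(t) < 0):
                first_bad = int(sub.index[np.flatnonzero(np.diff(t) < 0)[0] + 1])
                raise ValueError(
                    f"{path}: unsorted spike times for electrode {e}"
                    f" at line {first_bad + offset}"
                )
            trains[int(e)] = t
        out.append(SpikeTrainSet(str(chip), str(cond), file_dur, trains, meta_exc))
    return out


# ---------------------------------------------------------------------------
# raw traces (HDF5)
# ---------------------------------------------------------------------------


def write_raw_traces(traces: Iterable[RawTrace], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for tr in traces:
            ds = fh.create_dataset(f"electrode_{tr.electrode_id:03d}", data=tr.samples)
            ds.attrs["sampling_rate_hz"] = tr.sampling_rate_hz
            ds.attrs["electrode_id"] = tr.electrode_id
    return path


def read_raw_traces(path: str | Path) -> list[RawTrace]:
    with h5py.File(path, "r") as fh:
        out = []
        for name in sorted(fh):
            ds = fh[name]
            out.append(
                RawTrace(
                    electrode_id=int(ds.attrs["electrode_id"]),
                    sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                    samples=ds[...],
                )
            )
    return out


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

ARTIFACT_BEFORE_S = 0.006
ARTIFACT_AFTER_S = 0.025


def remove_artifacts(trace: RawTrace, positive_threshold: float) -> RawTrace:
    """Blank stimulation artifacts around positive threshold crossings.

    Every sample exceeding ``positive_threshold`` defines an artifact; the
    closed interval from 6 ms before to 25 ms after it is set to zero.  The
    continuous interval is mapped to sample indices by rounding outward
    (conservative blanking).  Idempotent.
    """
    if not positive_threshold > 0:
        raise ValueError("positive_threshold must be positive")
    s = trace.samples.copy()
    peaks = np.flatnonzero(s > positive_threshold)
    if peaks.size:
        fs = trace.sampling_rate_hz
        n_before = int(np.ceil(ARTIFACT_BEFORE_S * fs - 1e-9))
        n_after = int(np.ceil(ARTIFACT_AFTER_S * fs - 1e-9))
        starts = np.maximum(peaks - n_before, 0)
        ends = np.minimum(peaks + n_after, s.size - 1)
        delta = np.zeros(s.size + 1, dtype=int)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends + 1, -1)
        s[np.cumsum(delta[:-1]) > 0] = 0.0
    return RawTrace(trace.electrode_id, trace.sampling_rate_hz, s)


def detect_spikes(
    trace: RawTrace,
    dead_time_s: float = 0.001,
    sd_exclude_blanked: bool = False,
) -> np.ndarray:
    """Threshold-based spike detection on an artifact-cleaned trace.

    The detection threshold is -5 times the standard deviation of the signal.
    A spike is recorded at each negative-going threshold crossing (time of the
    first sample at or below threshold); crossings within ``dead_time_s`` of a
    previous accepted spike are suppressed.

    With ``sd_exclude_blanked`` the SD is computed over nonzero samples only,
    ignoring the zero stretches produced by artifact blanking.
    """
    s = trace.samples
    sel = s[s != 0] if sd_exclude_blanked else s
    sd = float(np.std(sel)) if sel.size else 0.0
    if sd == 0.0:
        logger.warning(
            "electrode %s: zero-variance trace, no spike threshold definable",
            trace.electrode_id,
        )
        return np.array([], dtype=float)
    threshold = -5.0 * sd
    below = s <= threshold
    prev_below = np.concatenate(([False], below[:-1]))
    crossings = np.flatnonzero(below & ~prev_below)
    if crossings.size == 0:
        return np.array([], dtype=float)
    dead_samples = dead_time_s * trace.sampling_rate_hz
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= dead_samples:
            kept.append(c)
    return np.asarray(kept, dtype=float) / trace.sampling_rate_hz


def active_electrodes(sts: SpikeTrainSet, min_spikes: int = 1) -> set[int]:
    """Indices of electrodes with at least ``min_spikes`` spikes, minus exclusions."""
    return {
        i
        for i, t in enumerate(sts.trains)
        if t.size >= min_spikes and i not in sts.excluded_electrodes
    }
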