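"""Paired pre/post-drug synthetic MEA recordings.

Emulates the study design that motivates the pipeline: 9 MEA chips, each
recorded for 600 s before and after application of a pro-convulsant
(bicuculline-like) drug that raises network synchrony.  Each electrode fires
homogeneous-Poisson background spikes; on top, chip-wide network-burst events
occur at Poisson times, and each electrode participating in an event (with a
participation probability) emits a fixed number of spikes jittered around the
event time.  The drug condition uses higher burst rate, higher participation
and tighter jitter -- i.e. more, larger, sharper network bursts, the hallmark
of disinhibition-induced hypersynchrony.

Both conditions of a chip share one multiplicative log-normal random effect on
all rates, so chips are heterogeneous but paired -- mirroring the
random-intercept assumption of the downstream linear mixed model.  A fraction
of electrodes is silenced per chip (both conditions) to emulate electrodes not
covered by active neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .spike_io import POST_DRUG, PRE_DRUG, SpikeTrainSet, write_spike_table

#: minimum separation of two spikes on one electrode (deduplication resolution)
DEDUP_RESOLUTION_S = 1e-4


@dataclass
class SynthConfig:
    """Generator configuration.

    Rates are per-second; probabilities in [0, 1].  The ``drug_*`` fields
    replace their baseline counterparts in the post-drug condition.
    """

    n_chips: int = 9
    n_electrodes: int = 60
    duration_s: float = 600.0
    bg_rate_hz: float = 0.5
    burst_rate_hz: float = 0.2
    burst_participation: float = 0.4
    spikes_per_burst: int = 5
    burst_jitter_s: float = 0.05
    chip_effect_sd: float = 0.2
    drug_participation: float = 0.9
    drug_jitter_s: float = 0.01
    drug_burst_rate_hz: float = 0.4
    silent_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bg_rate_hz", "burst_rate_hz", "drug_burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("burst_participation", "drug_participation", "silent_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    def null(self) -> "SynthConfig":
        """A copy in which the drug condition equals baseline (no effect)."""
        return replace(
            self,
            drug_participation=self.burst_participation,
            drug_jitter_s=self.burst_jitter_s,
            drug_burst_rate_hz=self.burst_rate_hz,
        )


def _simulate_condition(
    cfg: SynthConfig,
    rng: np.random.Generator,
    chip_id: str,
    condition: str,
    multiplier: float,
    silent: np.ndarray,
    burst_rate_hz: float,
    participation: float,
    jitter_s: float,
) -> SpikeTrainSet:
    T = cfg.duration_s
    n_events = rng.poisson(burst_rate_hz * multiplier * T)
    event_times = np.sort(rng.uniform(0.0, T, size=n_events))
    trains: list[np.ndarray] = []
    silent_set = set(int(i) for i in silent)
    for e in range(cfg.n_electrodes):
        if e in silent_set:
            # keep RNG stream aligned across conditions is not required;
            # silenced electrodes simply emit nothing
            trains.append(np.array([], dtype=float))
            continue
        n_bg = rng.poisson(cfg.bg_rate_hz * multiplier * T)
        t = rng.uniform(0.0, T, size=n_bg)
        if n_events:
            participates = rng.random(n_events) < participation
            ev = np.repeat(event_times[participates], cfg.spikes_per_burst)
            if ev.size:
                ev = ev + rng.normal(0.0, jitter_s, size=ev.size)
                t = np.concatenate([t, np.clip(ev, 0.0, T)])
        t = np.sort(t)
        if t.size > 1:
            keep = np.concatenate(([True], np.diff(t) >= DEDUP_RESOLUTION_S))
            t = t[keep]
        trains.append(t)
    return SpikeTrainSet(chip_id, condition, T, trains)


def generate_chip_pair(
    cfg: SynthConfig, chip_index: int
) -> tuple[SpikeTrainSet, SpikeTrainSet]:
    """Generate the paired (pre-drug, post-drug) recordings of one chip.

    Both conditions share the chip's multiplicative rate effect
    ``exp(N(0, chip_effect_sd^2))`` and the same set of silenced electrodes.
    """
    if not 0 <= chip_index < cfg.n_chips:
        raise ValueError(f"chip_index {chip_index} out of range [0, {cfg.n_chips})")
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(chip_index,))
    rng = np.random.default_rng(ss)
    multiplier = float(np.exp(rng.normal(0.0, cfg.chip_effect_sd)))
    n_silent = int(round(cfg.silent_fraction * cfg.n_electrodes))
    silent = rng.choice(cfg.n_electrodes, size=n_silent, replace=False)
    chip_id = f"chip{chip_index:02d}"
    pre = _simulate_condition(
        cfg, rng, chip_id, PRE_DRUG, multiplier, silent,
        cfg.burst_rate_hz, cfg.burst_participation, cfg.burst_jitter_s,
    )
    post = _simulate_condition(
        cfg, rng, chip_id, POST_DRUG, multiplier, silent,
        cfg.drug_burst_rate_hz, cfg.drug_participation, cfg.drug_jitter_s,
    )
    return pre, post


def generate_dataset(cfg: SynthConfig) -> list[tuple[SpikeTrainSet, SpikeTrainSet]]:
    """All ``n_chips`` chip pairs; fully reproducible from ``cfg.seed``."""
    return [generate_chip_pair(cfg, i) for i in range(cfg.n_chips)]


def write_dataset(
    pairs: list[tuple[SpikeTrainSet, SpikeTrainSet]], out_dir: str | Path
) -> list[Path]:
    """Write each recording as one spike-table CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pre, post in pairs:
        for sts in (pre, post):
            paths.append(
                write_spike_table(sts, out_dir / f"{sts.chip_id}_{sts.condition}.csv")
            )
    return paths
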