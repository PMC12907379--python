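"""Seizure baseline, onset detection and propagation mapping.

Applied to per-region rate traces: the baseline of a region is the
minimum rate over the relaxation window preceding the first event in the
seed (onset) region; a seizure onset is the first excursion exceeding the
baseline by a relative threshold (default 10%) sustained for a minimum
duration (default 100 ms), refined backward to the start of the monotonic
rise; the propagation map collects each region's onset delay relative to
the seed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OnsetConfig:
    """Thresholds of the onset detector."""

    rel_threshold: float = 0.10       # fractional rise above baseline
    min_duration: float = 100.0       # ms the trace must stay above
    refine_to_rise_start: bool = True  # backtrack to preceding local min

    def __post_init__(self) -> None:
        if self.rel_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_duration <= 0:
            raise ValueError("duration must be positive")


def baseline_rate(t: np.ndarray, trace: np.ndarray,
                  first_seed_event: float,
                  transient_end: float = 0.0) -> float:
    """Minimum rate over [transient_end, first_seed_event).

    The window is the relaxation phase preceding any event in the onset
    region; it must be nonempty.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    m = (t >= transient_end) & (t < first_seed_event)
    if not np.any(m):
        raise ValueError(
            f"no samples in the pre-event window "
            f"[{transient_end}, {first_seed_event})")
    return float(np.min(trace[m]))


def detect_onset(t: np.ndarray, trace: np.ndarray, baseline: float,
                 config: OnsetConfig | None = None,
                 t_start: float = 0.0) -> float | None:
    """First sustained excursion above baseline*(1+threshold), or None.

    The trace must exceed the threshold level and remain above it for at
    least ``min_duration`` ms; the reported onset is refined backward to
    the local minimum preceding the crossing (the start of the monotonic
    rise), unless refinement is disabled.
    """
    cfg = config or OnsetConfig()
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t = np.asarray(t, dtype=float)
    x = np.asarray(trace, dtype=float)
    level = baseline * (1.0 + cfg.rel_threshold)
    above = (x >= level) & (t >= t_start)
    if not np.any(above):
        return None
    # segment the above-level samples into runs, find the first run
    # lasting >= min_duration
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    for run in runs:
        if t[run[-1]] - t[run[0]] >= cfg.min_duration:
            k = run[0]
            if cfg.refine_to_rise_start:
                while k > 0 and x[k - 1] < x[k] and t[k - 1] >= t_start:
                    k -= 1
            return float(t[k])
    return None


@dataclass
class PropagationMap:
    """Per-region seizure onset delays relative to the seed region."""

    labels: list[str]
    seed_region: str
    seed_onset: float
    baselines: dict[str, float]
    onsets: dict[str, float | None]   # absolute onset time or None

    @property
    def delays(self) -> dict[str, float | None]:
        return {lab: (None if on is None else on - self.seed_onset)
                for lab, on in self.onsets.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.labels:
            on = self.onsets[lab]
            rows.append({
                "region": lab,
                "baseline": self.baselines[lab],
                "onset_ms": np.nan if on is None else on,
                "delay_ms": np.nan if on is None
                else on - self.seed_onset,
            })
        return pd.DataFrame(rows)


def propagation_map(t: np.ndarray, traces: np.ndarray, labels: list[str],
                    seed_region: str, first_seed_event: float,
                    config: OnsetConfig | None = None,
                    transient_end: float = 0.0) -> PropagationMap:
    """Onset delays of every region relative to the seed region.

    ``traces`` is (n_samples, n_regions); ``first_seed_event`` marks the
    first event in the seed region (end of the relaxation window used for
    baselines).  Regions without a qualifying excursion are marked absent
    (onset None).  Only the first qualifying onset per region is reported.
    """
    cfg = config or OnsetConfig()
    traces = np.asarray(traces, dtype=float)
    seed_idx = labels.index(seed_region)
    baselines: dict[str, float] = {}
    onsets: dict[str, float | None] = {}
    for j, lab in enumerate(labels):
        base = baseline_rate(t, traces[:, j], first_seed_event,
                             transient_end)
        baselines[lab] = base
        if base <= 0:
            onsets[lab] = None
            continue
        onsets[lab] = detect_onset(t, traces[:, j], base, cfg,
                                   t_start=transient_end)
    seed_onset = onsets[seed_region]
    if seed_onset is None:
        raise ValueError(
            f"seed region {seed_region!r} has no detected onset")
    return PropagationMap(labels=list(labels), seed_region=seed_region,
                          seed_onset=seed_onset, baselines=baselines,
                          onsets=onsets)
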