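"""Blockade-event detection and classification.

A blockade is a maximal interval where the current stays below a fixed
fraction (default 50%) of the open-pore baseline. Each detected event
carries its dwell time ``t_off``, the residual current (mean of the
blocked plateau, excluding a detected terminal dissociation spike), the
inter-event interval ``t_on``, a class label, and an ending-spike flag.

Classification follows the duplex-capture convention for these
experiments: blocks longer than 10 ms are attributed to captured DNA
duplexes; shorter blocks are unhybridized ssDNA, split into spike-like
(≤1 ms) and rectangular (1–10 ms) translocations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simulate import CLASS_LABELS, DUPLEX, RECT_SS, SPIKE_SS, EventTruth
from .trace import CurrentTrace

__all__ = [
    "DetectionParams",
    "BlockEvent",
    "BaselineEstimate",
    "BaselineError",
    "estimate_baseline",
    "detect_events",
    "classify_dwell",
    "event_frequency",
    "ssdna_frequency",
    "match_events",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]

EVENT_COLUMNS = [
    "start_s",
    "end_s",
    "t_off_s",
    "t_on_s",
    "residual_pa",
    "class",
    "ending_spike",
]


class BaselineError(RuntimeError):
    """Raised when no credible open-pore baseline can be found."""


@dataclass
class DetectionParams:
    """Tunable thresholds of the event detector.

    ``threshold_fraction`` sets block entry/exit at that fraction of the
    open-pore baseline; 0.5 cleanly separates the ~37–42 pA duplex
    residual levels from a ~150 pA open pore. The class thresholds encode
    the >10 ms duplex rule and the ≤1 ms spike rule.
    """

    threshold_fraction: float = 0.5
    min_event_samples: int = 2
    debounce_samples: int = 2
    baseline_window_s: float = 0.1
    duplex_threshold_s: float = 0.010
    spike_ss_max_s: float = 0.001
    spike_k_sd: float = 5.0  # terminal spike: >= k * noise SD below plateau
    min_open_fraction: float = 0.5
    edge_trim_samples: int = 2  # plateau samples dropped at each edge for the
    # residual mean, excluding filter-smeared transitions

    def validate(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.duplex_threshold_s <= self.spike_ss_max_s:
            raise ValueError("duplex_threshold_s must exceed spike_ss_max_s")
        if self.min_event_samples < 1 or self.debounce_samples < 1:
            raise ValueError("sample counts must be >= 1")


@dataclass
class BlockEvent:
    """One detected current blockade."""

    start_s: float
    end_s: float
    t_off_s: float
    residual_pa: float
    label: str
    ending_spike: bool = False
    t_on_s: float = float("nan")  # NaN for the first event of a trace

    def __post_init__(self) -> None:
        if self.t_off_s <= 0:
            raise ValueError("t_off_s must be > 0")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


class BaselineEstimate(NamedTuple):
    level_pa: float
    noise_sd_pa: float


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) indices of contiguous True runs."""
    if not mask.any():
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return starts, ends


def estimate_baseline(
    trace: CurrentTrace, params: DetectionParams | None = None
) -> BaselineEstimate:
    """Robust open-pore level and noise SD.

    Anchors the open level at a high quantile of the samples, thresholds at
    ``threshold_fraction`` of that anchor, and takes the median and scaled
    MAD of the above-threshold samples. Valid for traces blocked at most
    ~50% of the time; a mostly-blocked trace, or one with no contiguous
    open stretch of ``baseline_window_s``, raises :class:`BaselineError`.
    """
    params = params or DetectionParams()
    params.validate()
    x = trace.samples
    anchor = float(np.quantile(x, 0.999))
    thr = params.threshold_fraction * anchor
    open_mask = x > thr
    frac = float(open_mask.mean())
    if frac < params.min_open_fraction:
        raise BaselineError(
            f"only {frac:.0%} of samples lie above {thr:.1f} pA; trace is mostly "
            "blocked and the open-pore baseline cannot be estimated"
        )
    starts, ends = _true_runs(open_mask)
    need = int(round(params.baseline_window_s * trace.sampling_rate_hz))
    if not ((ends - starts) >= need).any():
        raise BaselineError(
            f"no open-pore stretch of at least {params.baseline_window_s} s "
            f"({need} samples) above {thr:.1f} pA"
        )
    open_samples = x[open_mask]
    level = float(np.median(open_samples))
    sd = float(1.4826 * np.median(np.abs(open_samples - level)))
    return BaselineEstimate(level, sd)


def classify_dwell(t_off_s: float, params: DetectionParams | None = None) -> str:
    """Apply the ≤1 ms / 1–10 ms / >10 ms classification rules to a dwell."""
    params = params or DetectionParams()
    if t_off_s <= params.spike_ss_max_s:
        return SPIKE_SS
    if t_off_s <= params.duplex_threshold_s:
        return RECT_SS
    return DUPLEX


def _terminal_spike(
    seg: np.ndarray, noise_sd: float, params: DetectionParams
) -> tuple[bool, float]:
    """Detect a terminal dissociation spike; return (flag, residual mean).

    The plateau is the segment median; a trailing run of samples at least
    ``spike_k_sd * noise_sd`` below it (and shorter than half the event)
    is flagged as the ending spike and excluded from the residual mean.
    """
    eps = max(params.spike_k_sd * noise_sd, 1e-9)
    plateau = float(np.median(seg))
    deep = seg < plateau - eps
    spike = False
    cut = seg.size
    deep_idx = np.flatnonzero(deep)
    # the deep run may stop a few samples short of the event end: the
    # low-pass filter smears the spike-to-open transition
    slack = 3
    if deep_idx.size and deep_idx[-1] >= seg.size - 1 - slack:
        j = int(deep_idx[-1])
        shallow_before = np.flatnonzero(~deep[: j + 1])
        run_start = int(shallow_before.max()) + 1 if shallow_before.size else 0
        if 2 <= j - run_start + 1 <= seg.size // 2:
            spike = True
            cut = run_start
    core = seg[:cut]
    trim = params.edge_trim_samples
    if core.size > 2 * trim + 1:
        core = core[trim : core.size - trim]
    return spike, float(core.mean())


def detect_events(
    trace: CurrentTrace, params: DetectionParams | None = None
) -> list[BlockEvent]:
    """Segment a trace into blockade events.

    Events are maximal below-threshold intervals after a short debounce
    (sub-``debounce_samples`` returns to baseline do not terminate an
    event); runs shorter than ``min_event_samples`` and events touching
    the trace boundaries are dropped. A blockade-free trace yields an
    empty list.
    """
    params = params or DetectionParams()
    params.validate()
    baseline, noise_sd = estimate_baseline(trace, params)
    thr = params.threshold_fraction * baseline
    fs = trace.sampling_rate_hz
    below = trace.samples < thr
    starts, ends = _true_runs(below)
    if starts.size == 0:
        return []
    # debounce: merge events separated by an above-threshold gap shorter
    # than debounce_samples
    merged: list[list[int]] = []
    for i0, i1 in zip(starts, ends):
        if merged and i0 - merged[-1][1] < params.debounce_samples:
            merged[-1][1] = i1
        else:
            merged.append([int(i0), int(i1)])
    events: list[BlockEvent] = []
    prev_end_s = math.nan
    for i0, i1 in merged:
        if i1 - i0 < params.min_event_samples:
            continue
        if i0 == 0 or i1 == trace.n_samples:  # partial event at a boundary
            continue
        seg = trace.samples[i0:i1]
        spike, residual = _terminal_spike(seg, noise_sd, params)
        t_off = (i1 - i0) / fs
        start_s = i0 / fs
        events.append(
            BlockEvent(
                start_s=start_s,
                end_s=i1 / fs,
                t_off_s=t_off,
                residual_pa=residual,
                label=classify_dwell(t_off, params),
                ending_spike=spike,
                t_on_s=start_s - prev_end_s,
            )
        )
        prev_end_s = i1 / fs
    return events


def event_frequency(
    events: Iterable[BlockEvent | EventTruth],
    trace_duration_s: float,
    classes: Sequence[str] | None = None,
) -> float:
    """Event rate (s⁻¹) of the given classes over a recording."""
    if trace_duration_s <= 0:
        raise ValueError("trace_duration_s must be > 0")
    wanted = set(classes) if classes is not None else set(CLASS_LABELS)
    unknown = wanted - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)}")
    n = sum(1 for ev in events if ev.label in wanted)
    return n / trace_duration_s


def ssdna_frequency(events: Iterable[BlockEvent | EventTruth], trace_duration_s: float) -> float:
    """Total ssDNA block frequency f_ss (spike-like + rectangular blocks)."""
    return event_frequency(events, trace_duration_s, classes=(SPIKE_SS, RECT_SS))


def match_events(
    truth: Sequence[EventTruth],
    detected: Sequence[BlockEvent],
    tol_s: float = 2e-3,
) -> list[tuple[EventTruth, BlockEvent]]:
    """Greedily pair truth and detected events by start time (within tol)."""
    pairs = []
    j = 0
    for ev in truth:
        while j < len(detected) and detected[j].start_s < ev.start_s - tol_s:
            j += 1
        if j < len(detected) and abs(detected[j].start_s - ev.start_s) <= tol_s:
            pairs.append((ev, detected[j]))
            j += 1
    return pairs


# ---------------------------------------------------------------------------
# Event-table CSV interchange
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[BlockEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [ev.start_s for ev in events],
            "end_s": [ev.end_s for ev in events],
            "t_off_s": [ev.t_off_s for ev in events],
            "t_on_s": [ev.t_on_s for ev in events],
            "residual_pa": [ev.residual_pa for ev in events],
            "class": [ev.label for ev in events],
            "ending_spike": [ev.ending_spike for ev in events],
        },
        columns=EVENT_COLUMNS,
    )


def write_events_csv(events: Sequence[BlockEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[BlockEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        BlockEvent(
            start_s=row.start_s,
            end_s=row.end_s,
            t_off_s=row.t_off_s,
            residual_pa=row.residual_pa,
            label=row["class"],
            ending_spike=bool(row.ending_spike),
            t_on_s=float(row.t_on_s),
        )
        for _, row in df.iterrows()
    ]
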