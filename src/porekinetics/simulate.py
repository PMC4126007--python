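"""Seeded simulator of α-hemolysin single-channel recordings.

The generator emulates the statistical structure of duplex-capture
experiments: a constant open-pore current with Gaussian noise, sampled at
20 kHz and optionally low-pass filtered at 5 kHz (4-pole Bessel, bilinear
design), interrupted by Poisson-arrival blockade events of three classes —

* ``spike_ss``  — spike-like ssDNA translocations (~200 µs),
* ``rect_ss``   — rectangular ssDNA blocks (1–10 ms),
* ``duplex``    — captured DNA duplexes (>10 ms; exponential or
  two-component exponential dwell, species-specific residual level, and
  optionally a brief deeper "ending spike" marking strand dissociation).

A single pore can hold one molecule at a time, so overlapping arrivals are
resolved by a single-occupancy queue: a later arrival is deferred until
shortly after the previous block ends.

Internally currents are pA and times are seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

SPIKE_SS = "spike_ss"
RECT_SS = "rect_ss"
DUPLEX = "duplex"
CLASS_LABELS = (SPIKE_SS, RECT_SS, DUPLEX)

# Class dwell windows used both for truncating ssDNA dwell draws (so the
# generated label is consistent with the >10 ms / <1 ms classification
# rules) and, with a small safety margin, to keep dwells away from the
# class boundaries where a ±1-sample measurement error could flip a label.
SPIKE_MAX_S = 0.001
DUPLEX_MIN_S = 0.010
_SPIKE_WINDOW = (1.5e-4, 0.9e-3)
_RECT_WINDOW = (1.2e-3, 9.5e-3)

#: Minimum open-pore gap enforced between queued events (s); long enough
#: for the detector's 2-sample debounce at 20 kHz with the 5 kHz filter.
MIN_GAP_S = 5e-4

TRUTH_COLUMNS = ["start_s", "dwell_s", "class", "residual_pa", "component"]


@dataclass
class EventClassSpec:
    """Generative description of one blockade class.

    ``dwell_components`` is a list of ``(mean_dwell_s, weight)`` pairs of an
    exponential mixture; ``residual_sd_pa`` is the event-to-event spread of
    the blocked level (sample noise is added separately at render time).
    """

    label: str
    arrival_rate_hz: float
    dwell_components: list[tuple[float, float]]
    residual_mean_pa: float
    residual_sd_pa: float = 0.0
    ending_spike: bool = False
    ending_spike_depth_pa: float | None = None  # None -> 50% of residual level
    ending_spike_width_s: float = 0.001

    def validate(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown event class {self.label!r}")
        if self.arrival_rate_hz < 0:
            raise ValueError("arrival_rate_hz must be >= 0")
        if not self.dwell_components:
            raise ValueError("dwell_components must be non-empty")
        taus = [t for t, _ in self.dwell_components]
        weights = [w for _, w in self.dwell_components]
        if any(t <= 0 for t in taus):
            raise ValueError("all mean dwells must be > 0")
        if any(w <= 0 for w in weights) or not math.isclose(sum(weights), 1.0, rel_tol=1e-9):
            raise ValueError("dwell component weights must be positive and sum to 1")
        if self.residual_sd_pa < 0:
            raise ValueError("residual_sd_pa must be >= 0")
        if self.ending_spike and self.label != DUPLEX:
            raise ValueError("ending_spike is a duplex-only feature")

    def mean_dwell_s(self) -> float:
        return sum(t * w for t, w in self.dwell_components)

    def sample_dwell(self, rng: np.random.Generator) -> tuple[float, int]:
        """Draw (dwell_s, component_index).

        ssDNA classes use exponentials truncated to their class window so
        the generated label obeys the classification rules; duplex dwells
        are untruncated (unbiased for dwell-time fitting).
        """
        weights = np.array([w for _, w in self.dwell_components])
        comp = int(rng.choice(len(weights), p=weights / weights.sum()))
        tau = self.dwell_components[comp][0]
        lo, hi = {
            SPIKE_SS: _SPIKE_WINDOW,
            RECT_SS: _RECT_WINDOW,
            DUPLEX: (DUPLEX_MIN_S, math.inf),
        }[self.label]
        if self.label == DUPLEX:
            return float(rng.exponential(tau)), comp
        for _ in range(10_000):
            d = float(rng.exponential(tau))
            if lo <= d <= hi:
                return d, comp
        raise RuntimeError(
            f"could not draw a {self.label} dwell in [{lo}, {hi}] s from tau={tau}"
        )


@dataclass
class SimulationConfig:
    """Conditions of one simulated recording."""

    duration_s: float
    species: list[EventClassSpec] = field(default_factory=list)
    sampling_rate_hz: float = 20_000.0
    open_current_pa: float = 150.0
    noise_sd_pa: float = 2.0
    voltage_mv: float = 150.0  # metadata only
    filter_cutoff_hz: float | None = 5_000.0
    seed: int | None = None

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be >= 0")
        if self.filter_cutoff_hz is not None and not (
            self.sampling_rate_hz > 2 * self.filter_cutoff_hz
        ):
            raise ValueError("sampling_rate_hz must exceed twice the filter cutoff")
        for spec in self.species:
            spec.validate()

    def expected_duty_cycle(self) -> float:
        return sum(s.arrival_rate_hz * s.mean_dwell_s() for s in self.species)


@dataclass
class EventTruth:
    """Ground truth for one placed blockade event."""

    start_s: float
    dwell_s: float
    label: str
    residual_mean_pa: float
    component: int
    ending_spike: bool = False
    spike_level_pa: float = float("nan")
    spike_width_s: float = 0.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.dwell_s


def sample_event_train(
    config: SimulationConfig, seed: int | None = None
) -> list[EventTruth]:
    """Draw the blockade event train for one recording.

    Per-class arrivals are homogeneous Poisson processes; dwells come from
    each class's exponential mixture. Arrivals that would overlap the
    previous block are deferred to just after it ends (single-occupancy
    queue). Returns the truth table sorted by start time.

    Raises ``ValueError`` if the configured expected duty cycle exceeds
    0.5 — such a trace would be mostly blocked and the open-pore baseline
    would no longer be estimable.
    """
    config.validate()
    duty = config.expected_duty_cycle()
    if duty > 0.5:
        raise ValueError(
            f"expected event duty cycle {duty:.2f} exceeds 0.5; "
            "reduce arrival rates or mean dwells"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    events: list[EventTruth] = []
    for spec in config.species:
        if spec.arrival_rate_hz <= 0:
            continue
        t = 0.0
        while True:
            t += rng.exponential(1.0 / spec.arrival_rate_hz)
            if t >= config.duration_s:
                break
            dwell, comp = spec.sample_dwell(rng)
            level = spec.residual_mean_pa
            if spec.residual_sd_pa > 0:
                level = float(rng.normal(level, spec.residual_sd_pa))
            spike = bool(spec.ending_spike and dwell >= 2 * spec.ending_spike_width_s)
            depth = (
                spec.ending_spike_depth_pa
                if spec.ending_spike_depth_pa is not None
                else 0.5 * spec.residual_mean_pa
            )
            events.append(
                EventTruth(
                    start_s=t,
                    dwell_s=dwell,
                    label=spec.label,
                    residual_mean_pa=level,
                    component=comp,
                    ending_spike=spike,
                    spike_level_pa=level - depth if spike else float("nan"),
                    spike_width_s=spec.ending_spike_width_s if spike else 0.0,
                )
            )
    events.sort(key=lambda ev: ev.start_s)
    # single-occupancy queue: defer arrivals into the previous block
    cursor = -math.inf
    for ev in events:
        if ev.start_s < cursor + MIN_GAP_S:
            ev.start_s = cursor + MIN_GAP_S
        cursor = ev.end_s
    return [ev for ev in events if ev.end_s <= config.duration_s]


def render_trace(
    truth: list[EventTruth], config: SimulationConfig, seed: int | None = None
):
    """Render an event train into a :class:`~porekinetics.trace.CurrentTrace`.

    The baseline sits at ``open_current_pa``; each event drops the level to
    its residual mean for its dwell, duplex events optionally end with a
    deeper rectangular spike, Gaussian sample noise is added, and the
    optional low-pass filter is applied last.
    """
    from .trace import CurrentTrace

    config.validate()
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    level = np.full(n, config.open_current_pa, dtype=float)
    prev_end = -math.inf
    for ev in truth:
        if ev.start_s < prev_end:
            raise ValueError("truth events overlap; run sample_event_train first")
        prev_end = ev.end_s
        i0 = int(round(ev.start_s * fs))
        i1 = min(int(round(ev.end_s * fs)), n)
        level[i0:i1] = ev.residual_mean_pa
        if ev.ending_spike:
            j0 = max(int(round((ev.end_s - ev.spike_width_s) * fs)), i0)
            level[j0:i1] = ev.spike_level_pa
    x = level
    if config.noise_sd_pa > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        x = x + rng.normal(0.0, config.noise_sd_pa, size=n)
    if config.filter_cutoff_hz is not None:
        sos = signal.bessel(
            4, config.filter_cutoff_hz, btype="low", fs=fs, output="sos", norm="mag"
        )
        x = signal.sosfilt(sos, x)
    return CurrentTrace(
        samples=x,
        sampling_rate_hz=fs,
        metadata={"voltage_mv": config.voltage_mv, "seed": config.seed},
    )


def simulate_recording(config: SimulationConfig, seed: int | None = None):
    """Convenience wrapper: sample a train and render it with one seed."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    s_train, s_render = (int(s) for s in root.integers(0, 2**31 - 1, size=2))
    truth = sample_event_train(config, seed=s_train)
    trace = render_trace(truth, config, seed=s_render)
    return truth, trace


# ---------------------------------------------------------------------------
# Truth-table CSV interchange
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[EventTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [ev.start_s for ev in truth],
            "dwell_s": [ev.dwell_s for ev in truth],
            "class": [ev.label for ev in truth],
            "residual_pa": [ev.residual_mean_pa for ev in truth],
            "component": [ev.component for ev in truth],
            "ending_spike": [ev.ending_spike for ev in truth],
            "spike_level_pa": [ev.spike_level_pa for ev in truth],
            "spike_width_s": [ev.spike_width_s for ev in truth],
        }
    )


def write_truth_csv(truth: list[EventTruth], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[EventTruth]:
    df = pd.read_csv(path)
    return [
        EventTruth(
            start_s=row.start_s,
            dwell_s=row.dwell_s,
            label=row["class"],
            residual_mean_pa=row.residual_pa,
            component=int(row.component),
            ending_spike=bool(row.get("ending_spike", False)),
            spike_level_pa=float(row.get("spike_level_pa", float("nan"))),
            spike_width_s=float(row.get("spike_width_s", 0.0)),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------
#
# Dwell-time peaks (s) and residual-current peaks (pA, with relative
# weights) for the 16-nt probe/target duplexes carrying a single C-C,
# mC-C or hmC-C mismatch, with and without Ag+, plus the bare ssDNA
# probe. Values are the fitted peaks reported for these systems; the
# 0.3/0.7 split of the two C-Ag-C dwell components is a modelling choice
# (only the peak positions are reported).

DUPLEX_CONDITIONS: dict[str, dict] = {
    "cc": {"dwell": [(0.059, 1.0)], "residual": [(41.5, 1.0)]},
    "cc_ag": {"dwell": [(0.051, 0.3), (0.384, 0.7)], "residual": [(36.8, 1.0)]},
    "mc": {"dwell": [(0.069, 1.0)], "residual": [(37.4, 1.0)]},
    "mc_ag": {"dwell": [(0.092, 1.0)], "residual": [(33.9, 0.5), (38.1, 0.5)]},
    "hmc": {"dwell": [(0.0196, 1.0)], "residual": [(36.3, 1.0)]},
    "hmc_ag": {"dwell": [(0.0173, 1.0)], "residual": [(36.2, 1.0)]},
}

#: ssDNA probe residual level (pA) and spread from its blockade histogram.
SS_RESIDUAL_PA = (17.4, 0.84)

#: Total ssDNA block frequencies (s^-1) in the 8 µM/8 µM probe/target
#: mixture, without and with Ag+.
F_SS_MIXTURE_HZ = {"no_ag": 6.52, "with_ag": 4.10}


def condition_species(
    condition: str,
    duplex_rate_hz: float = 0.5,
    ss_rate_hz: float | None = None,
    residual_sd_pa: float = 0.8,
    ending_spike: bool = True,
) -> list[EventClassSpec]:
    """Event-class specs emulating one experimental condition.

    ``condition`` is one of ``cc, cc_ag, mc, mc_ag, hmc, hmc_ag``. The total
    ssDNA rate defaults to the measured mixture block frequency for the
    matching ±Ag+ condition and is split evenly between the spike-like and
    rectangular classes; multi-peak residual conditions are expanded into
    one duplex spec per residual peak with the rate split by peak weight.
    """
    if condition not in DUPLEX_CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; choose from {sorted(DUPLEX_CONDITIONS)}")
    cond = DUPLEX_CONDITIONS[condition]
    if ss_rate_hz is None:
        ss_rate_hz = F_SS_MIXTURE_HZ["with_ag" if condition.endswith("_ag") else "no_ag"]
    ss_mean, ss_sd = SS_RESIDUAL_PA
    species = [
        EventClassSpec(SPIKE_SS, ss_rate_hz / 2, [(2.5e-4, 1.0)], ss_mean, ss_sd),
        EventClassSpec(RECT_SS, ss_rate_hz / 2, [(3e-3, 1.0)], ss_mean, ss_sd),
    ]
    for res_mean, res_w in cond["residual"]:
        species.append(
            EventClassSpec(
                DUPLEX,
                duplex_rate_hz * res_w,
                list(cond["dwell"]),
                res_mean,
                residual_sd_pa,
                ending_spike=ending_spike,
            )
        )
    return species


def demo_config(
    condition: str = "cc_ag", duration_s: float = 300.0, seed: int | None = 0, **kwargs
) -> SimulationConfig:
    """A ready-made recording config for one study condition."""
    return SimulationConfig(
        duration_s=duration_s, species=condition_species(condition, **kwargs), seed=seed
    )
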