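"""Duplex hybridization equilibrium from nanopore block frequencies.

For a symmetric 1:1 mixture of two complementary strands (each at initial
concentration S = [ssDNA]_0,total / 2), the free concentration of each
strand at equilibrium is estimated from the total ssDNA block frequency
f_ss and the averaged single-strand capture rate k_on:

    c  = f_ss / (2 k_on)                [µM]
    Kd = c² / (S − c)                   [µM]

which is the block-frequency form Kd = (f_ss/k_on)² / 2([ssDNA]_0 −
f_ss/k_on) with [ssDNA]_0 read as the *total* ssDNA concentration (both
strands). The apparent shift in duplex dissociation energy produced by a
stabilizing ligand follows from the ratio of dwell-time peaks,

    ΔE = R·T·ln(τ_after / τ_before)    [J/mol],

with R = 8.314 J·mol⁻¹·K⁻¹ and T defaulting to 295.15 K (22 °C).

All aggregates use the sample standard deviation (n−1 denominator);
internal arithmetic is double precision, with presentation rounding kept
at the reporting layer (:func:`round_display`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default experiment temperature, K (recordings at 22 ± 1 °C).
DEFAULT_TEMPERATURE_K = 295.15

#: Measured capture-rate and block-frequency replicates for the 16-nt
#: C-C probe/target system in the 8 µM/8 µM mixture: per-strand capture
#: rates (µM⁻¹ s⁻¹) for the cytosine target strand and its common probe,
#: and total ssDNA block frequencies (s⁻¹) in the mixture without/with
#: Ag⁺. ``kon_reported_means`` are the strand-mean capture rates as
#: reported alongside the replicates (the probe value, 3.49, differs from
#: the arithmetic mean of its replicates, 3.44; both are kept).
CC_MIXTURE_MEASUREMENTS: dict = {
    "kon_replicates": {
        "target_c": [3.60, 3.41, 3.73, 3.88, 3.80],
        "probe": [3.31, 3.78, 3.33, 3.36, 3.02, 3.84],
    },
    "kon_reported_means": {"target_c": 3.68, "probe": 3.49},
    "fss_replicates": {
        "no_ag": [6.21, 6.25, 6.57, 7.03],
        "with_ag": [3.81, 4.20, 4.23, 4.17],
    },
    "ssdna0_total_um": 16.0,
}


def round_display(x: float, ndigits: int) -> float:
    """Half-up decimal rounding for presentation (3.685 -> 3.69).

    Floating-point representation error is absorbed by first formatting
    to 9 decimals, so a mean that is exactly 6.515 in decimal arithmetic
    rounds up to 6.52 rather than down via its float image 6.51499…
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.9f}").quantize(q, rounding=ROUND_HALF_UP))


def estimate_kon(block_frequency_hz: float, concentration_um: float) -> float:
    """Capture rate k_on = block frequency / analyte concentration (µM⁻¹ s⁻¹)."""
    if concentration_um <= 0:
        raise ValueError("concentration_um must be > 0")
    if block_frequency_hz < 0:
        raise ValueError("block_frequency_hz must be >= 0")
    return block_frequency_hz / concentration_um


def estimate_kd(f_ss_hz: float, k_on_um_s: float, ssdna0_total_um: float) -> float:
    """Equilibrium dissociation constant (µM) from the ssDNA block frequency.

    ``ssdna0_total_um`` is the total initial ssDNA concentration, both
    strands combined (16 µM for an 8 µM + 8 µM mixture). Raises
    ``ValueError`` when the implied free concentration reaches a strand's
    initial concentration (inputs would imply more free ssDNA than the
    mixture contains).
    """
    if k_on_um_s <= 0:
        raise ValueError("k_on_um_s must be > 0")
    if ssdna0_total_um <= 0:
        raise ValueError("ssdna0_total_um must be > 0")
    if f_ss_hz < 0:
        raise ValueError("f_ss_hz must be >= 0")
    c = f_ss_hz / (2.0 * k_on_um_s)  # free concentration of each strand
    s0 = ssdna0_total_um / 2.0  # each strand's initial concentration
    if c >= s0:
        raise ValueError(
            f"implied free strand concentration {c:.3g} µM is not below the "
            f"initial {s0:.3g} µM; f_ss and k_on are inconsistent with the mixture"
        )
    return c * c / (s0 - c)


def implied_fss(kd_um: float, k_on_um_s: float, ssdna0_total_um: float) -> float:
    """Invert :func:`estimate_kd`: the ssDNA block frequency a mixture with
    the given Kd would show. Solves c² + Kd·c − S·Kd = 0 for the free
    strand concentration c, then f_ss = 2·k_on·c."""
    if kd_um < 0:
        raise ValueError("kd_um must be >= 0")
    s0 = ssdna0_total_um / 2.0
    c = 0.5 * (-kd_um + math.sqrt(kd_um * kd_um + 4.0 * s0 * kd_um))
    return 2.0 * k_on_um_s * c


def delta_energy(
    tau_before_s: float,
    tau_after_s: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Apparent dissociation-energy shift R·T·ln(τ_after/τ_before) in J/mol.

    Antisymmetric under swapping the two dwell times; zero iff the ratio
    is 1.
    """
    if tau_before_s <= 0 or tau_after_s <= 0:
        raise ValueError("dwell times must be > 0")
    if temperature_k <= 0:
        raise ValueError("temperature_k must be > 0")
    return R_GAS * temperature_k * math.log(tau_after_s / tau_before_s)


def fold_change(tau_after_s: float, tau_before_s: float) -> float:
    """Dwell-time (or frequency) ratio after/before."""
    if tau_before_s <= 0 or tau_after_s <= 0:
        raise ValueError("values must be > 0")
    return tau_after_s / tau_before_s


def propagate_difference_error(sd_a: float, sd_b: float) -> float:
    """SD of a difference of independent quantities: sqrt(sd_a² + sd_b²)."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.hypot(sd_a, sd_b)


@dataclass
class ColumnAggregate:
    mean: float
    sd: float  # NaN (and flagged) for a single replicate
    n: int

    @property
    def single_replicate(self) -> bool:
        return self.n < 2


def _aggregate(values: Sequence[float]) -> ColumnAggregate:
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    return ColumnAggregate(mean=float(v.mean()), sd=sd, n=int(v.size))


@dataclass
class EquilibriumResult:
    """Per-replicate and aggregated equilibrium quantities for a mixture.

    ``kd_replicates`` holds one Kd per f_ss replicate and condition,
    computed with the capture rate averaged across the two strands.
    """

    ssdna0_total_um: float
    k_on_um_s: float
    kon_strand_means: dict[str, float]
    kon_replicates: dict[str, list[float]]
    fss_replicates: dict[str, list[float]]
    kd_replicates: dict[str, list[float]]
    aggregates: dict[str, ColumnAggregate] = field(default_factory=dict)

    @property
    def single_replicate_columns(self) -> list[str]:
        return [k for k, agg in self.aggregates.items() if agg.single_replicate]

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one column per measured/derived quantity,
        replicates as rows, aggregate mean and SD as the last two rows."""
        cols: dict[str, list[float]] = {}
        for strand, reps in self.kon_replicates.items():
            cols[f"kon_{strand}_um_s"] = list(reps)
        for cond, reps in self.fss_replicates.items():
            cols[f"fss_{cond}_hz"] = list(reps)
        for cond, reps in self.kd_replicates.items():
            cols[f"kd_{cond}_um"] = list(reps)
        depth = max(len(v) for v in cols.values())
        data = {
            k: v + [float("nan")] * (depth - len(v)) + [self.aggregates[k].mean, self.aggregates[k].sd]
            for k, v in cols.items()
        }
        index = [f"rep{i + 1}" for i in range(depth)] + ["mean", "sd"]
        return pd.DataFrame(data, index=index)

    def to_dict(self) -> dict:
        return {
            "ssdna0_total_um": self.ssdna0_total_um,
            "k_on_um_s": self.k_on_um_s,
            "kon_strand_means": self.kon_strand_means,
            "kon_replicates": self.kon_replicates,
            "fss_replicates": self.fss_replicates,
            "kd_replicates": self.kd_replicates,
            "aggregates": {
                k: {"mean": a.mean, "sd": a.sd, "n": a.n}
                for k, a in self.aggregates.items()
            },
            "single_replicate_columns": self.single_replicate_columns,
        }


def build_table2(
    kon_replicates: Mapping[str, Sequence[float]],
    fss_replicates: Mapping[str, Sequence[float]],
    ssdna0_total_um: float = 16.0,
    kon_strand_means: Mapping[str, float] | None = None,
) -> EquilibriumResult:
    """Assemble the full equilibrium table for a 1:1 strand mixture.

    ``kon_replicates`` maps each strand to its pooled capture-rate
    replicates; ``fss_replicates`` maps each condition (e.g. with/without
    a stabilizing ligand) to its paired per-experiment block frequencies.
    Kd is computed per f_ss replicate with the capture rate averaged over
    the strand means, then aggregated as mean ± sample SD. Passing
    ``kon_strand_means`` overrides the replicate-derived strand means
    (e.g. to use independently reported values).
    """
    if not kon_replicates or not fss_replicates:
        raise ValueError("need at least one strand and one f_ss condition")
    for name, reps in {**dict(kon_replicates), **dict(fss_replicates)}.items():
        if len(reps) < 1:
            raise ValueError(f"column {name!r} has no replicates")
    strand_means = {
        s: (
            float(kon_strand_means[s])
            if kon_strand_means is not None
            else float(np.mean(reps))
        )
        for s, reps in kon_replicates.items()
    }
    k_bar = float(np.mean(list(strand_means.values())))
    kd_replicates = {
        cond: [estimate_kd(f, k_bar, ssdna0_total_um) for f in reps]
        for cond, reps in fss_replicates.items()
    }
    aggregates: dict[str, ColumnAggregate] = {}
    for strand, reps in kon_replicates.items():
        aggregates[f"kon_{strand}_um_s"] = _aggregate(reps)
    for cond, reps in fss_replicates.items():
        aggregates[f"fss_{cond}_hz"] = _aggregate(reps)
        aggregates[f"kd_{cond}_um"] = _aggregate(kd_replicates[cond])
    return EquilibriumResult(
        ssdna0_total_um=float(ssdna0_total_um),
        k_on_um_s=k_bar,
        kon_strand_means=strand_means,
        kon_replicates={s: [float(x) for x in v] for s, v in kon_replicates.items()},
        fss_replicates={c: [float(x) for x in v] for c, v in fss_replicates.items()},
        kd_replicates=kd_replicates,
        aggregates=aggregates,
    )


def reference_equilibrium_table(use_reported_kon_means: bool = True) -> EquilibriumResult:
    """The packaged C-C mixture dataset run through :func:`build_table2`.

    With ``use_reported_kon_means`` (default) the strand means are the
    reported 3.68/3.49 µM⁻¹ s⁻¹ values; otherwise they are recomputed
    from the replicates (3.684/3.44 — the probe column's reported mean is
    not the arithmetic mean of its replicates).
    """
    m = CC_MIXTURE_MEASUREMENTS
    return build_table2(
        m["kon_replicates"],
        m["fss_replicates"],
        ssdna0_total_um=m["ssdna0_total_um"],
        kon_strand_means=m["kon_reported_means"] if use_reported_kon_means else None,
    )
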