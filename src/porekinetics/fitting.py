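"""Dwell-time and residual-current distribution fitting.

Dwell times of single-molecule blockades are fitted as exponential
mixtures by maximum likelihood on the raw dwells,

    f(t) = Σᵢ wᵢ (1/τᵢ) exp(−t/τᵢ),

whose log-time representation f(log t) = Σᵢ wᵢ (t/τᵢ) exp(−t/τᵢ)·ln10 is
the familiar peaked display form: for a single exponential the log-time
density peaks exactly at t = τ, so fitted τ values are directly the peak
dwell times read off a log-binned histogram. Working on raw dwells keeps
the estimate independent of any binning; the log axis is used for
initialization and display.

Residual-current histograms are fitted as Gaussian mixtures
(scikit-learn EM with deterministic quantile initialization).

Peak standard errors follow the nonparametric bootstrap (200 seeded
resamples by default), matching the ± convention of single-channel
dwell analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

LN10 = math.log(10.0)


class FitError(RuntimeError):
    """Raised on degenerate inputs, component collapse, or non-convergence."""


# ---------------------------------------------------------------------------
# Log-axis dwell histogram
# ---------------------------------------------------------------------------

class LogDwellHistogram(NamedTuple):
    """Counts on a uniform log10(t) grid; bin centers sit on multiples of
    the bin width so a dwell of exactly 10^k falls in its own bin."""

    counts: np.ndarray
    edges_log10: np.ndarray

    @property
    def centers_log10(self) -> np.ndarray:
        return 0.5 * (self.edges_log10[:-1] + self.edges_log10[1:])

    @property
    def mode_log10(self) -> float:
        return float(self.centers_log10[int(np.argmax(self.counts))])


def log_dwell_histogram(
    dwells: Sequence[float], bins_per_decade: int = 10
) -> LogDwellHistogram:
    """Bin dwell times uniformly in log10(t); counts conserve n."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("no dwell times given")
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("dwell times must be finite and > 0")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    w = 1.0 / bins_per_decade
    logs = np.log10(d)
    lo = math.floor(logs.min() / w) * w - 0.5 * w
    hi = math.ceil(logs.max() / w) * w + 0.5 * w
    nbins = int(round((hi - lo) / w))
    edges = lo + w * np.arange(nbins + 1)
    counts, _ = np.histogram(logs, bins=edges)
    return LogDwellHistogram(counts=counts, edges_log10=edges)


# ---------------------------------------------------------------------------
# Exponential-mixture dwell fit
# ---------------------------------------------------------------------------

@dataclass
class DwellFit:
    """Exponential (mixture) dwell-time model.

    ``components`` are (tau_s, weight) pairs sorted by tau ascending;
    ``peak_dwells_s`` are the modes of the log-time density, which for an
    exponential mixture coincide with the component taus. ``uncertainties``
    are per-peak bootstrap SEs (NaN when bootstrapping was disabled).
    """

    n_components: int
    components: list[tuple[float, float]]
    peak_dwells_s: list[float]
    uncertainties: list[float]
    log_likelihood: float
    n_obs: int
    converged: bool = True
    weight_uncertainties: list[float] | None = None

    @property
    def taus_s(self) -> list[float]:
        return [t for t, _ in self.components]

    @property
    def weights(self) -> list[float]:
        return [w for _, w in self.components]

    @property
    def n_parameters(self) -> int:
        return 2 * self.n_components - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * math.log(self.n_obs)

    def log_time_density(self, t: np.ndarray) -> np.ndarray:
        """Density on the log10(t) axis evaluated at dwell values t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for tau, w in self.components:
            out += w * (t / tau) * np.exp(-t / tau)
        return out * LN10


def _check_dwells(d: np.ndarray, n_components: int) -> None:
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("dwell times must be finite and > 0")
    if d.size < 10 * n_components:
        raise FitError(
            f"need at least {10 * n_components} dwells for {n_components} "
            f"component(s); got {d.size}"
        )
    if np.ptp(d) == 0:
        raise FitError("all dwell times identical; zero-variance input cannot be fitted")


def _quantile_init(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Split the sorted sample into k contiguous groups; group means seed
    the taus. Deterministic, so EM restarts are reproducible."""
    srt = np.sort(d)
    groups = np.array_split(srt, k)
    tau0 = np.array([max(g.mean(), 1e-12) for g in groups])
    # nudge exact ties apart so EM can separate them
    for i in range(1, k):
        if tau0[i] <= tau0[i - 1]:
            tau0[i] = tau0[i - 1] * 1.05
    return tau0, np.full(k, 1.0 / k)


def _exp_mixture_em(
    d: np.ndarray,
    tau0: np.ndarray,
    w0: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    tau, w = tau0.copy(), w0.copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = (w / tau) * np.exp(-d[:, None] / tau)  # (n, k)
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / d.size
        tau = (resp * d[:, None]).sum(axis=0) / nk
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return tau, w, ll, converged


def _fit_exp_once(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    if k == 1:
        tau = float(d.mean())
        ll = float(-d.size * math.log(tau) - d.sum() / tau)
        return np.array([tau]), np.array([1.0]), ll, True
    tau0, w0 = _quantile_init(d, k)
    tau, w, ll, converged = _exp_mixture_em(d, tau0, w0)
    order = np.argsort(tau)
    tau, w = tau[order], w[order]
    if np.any(w < 1e-4):
        raise FitError("mixture collapsed: a component weight vanished")
    if np.any(tau[1:] / tau[:-1] < 1.02):
        raise FitError("mixture collapsed: component taus are indistinguishable")
    return tau, w, ll, converged


def fit_log_exponential(
    dwells: Sequence[float],
    n_components: int = 1,
    seed: int | None = None,
    n_bootstrap: int = 200,
    truncation_s: float | None = None,
) -> DwellFit:
    """Maximum-likelihood exponential (mixture) fit of dwell times.

    Deterministic given ``seed`` (quantile initialization; the seed only
    drives the bootstrap resampling for the peak SEs). Raises
    :class:`FitError` on too-few or zero-variance dwells, component
    collapse, or non-convergence.

    ``truncation_s`` handles left-truncated samples (e.g. duplex dwells
    kept only above the 10 ms classification threshold): by memorylessness
    each component is exponential in t − t₀ beyond the truncation point
    t₀, so the fit runs on the shifted dwells and the taus are unbiased;
    the reported weights are then the component fractions *within the
    truncated regime* (long components are over-represented relative to
    the untruncated mixture).
    """
    d = np.asarray(dwells, dtype=float)
    if truncation_s is not None:
        if np.any(d <= truncation_s):
            raise ValueError(
                f"all dwells must exceed the truncation point {truncation_s} s"
            )
        d = d - truncation_s
    _check_dwells(d, n_components)
    tau, w, ll, converged = _fit_exp_once(d, n_components)
    if not converged:
        raise FitError(
            f"EM did not converge for {n_components} components on n={d.size}"
        )
    ses = [float("nan")] * n_components
    wses = [float("nan")] * n_components
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        taus_bs, ws_bs = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, d.size, size=d.size)
            try:
                tb, wb, _, conv = _fit_exp_once(d[idx], n_components)
            except FitError:
                continue
            if conv:
                taus_bs.append(tb)
                ws_bs.append(wb)
        if len(taus_bs) >= max(20, n_bootstrap // 2):
            ses = list(np.std(np.array(taus_bs), axis=0, ddof=1))
            wses = list(np.std(np.array(ws_bs), axis=0, ddof=1))
        # else: leave SEs as NaN — the resampled fits were too unstable
    return DwellFit(
        n_components=n_components,
        components=[(float(t), float(wi)) for t, wi in zip(tau, w)],
        peak_dwells_s=[float(t) for t in tau],
        uncertainties=[float(s) for s in ses],
        log_likelihood=ll,
        n_obs=int(d.size),
        converged=converged,
        weight_uncertainties=[float(s) for s in wses],
    )


class ModelChoice(NamedTuple):
    n_components: int
    low_confidence: bool
    bic: dict[int, float]


def model_selection(
    dwells: Sequence[float],
    max_components: int = 2,
    seed: int | None = None,
    truncation_s: float | None = None,
) -> ModelChoice:
    """BIC-selected exponential component count (ties favor fewer).

    Candidate counts needing more than n/10 components are not attempted;
    if that rules out some requested candidates the choice is flagged
    low-confidence (e.g. n = 15 returns 1, flagged).
    """
    if not 1 <= max_components <= 3:
        raise ValueError("max_components must be between 1 and 3")
    d = np.asarray(dwells, dtype=float)
    bics: dict[int, float] = {}
    underpowered = False
    for k in range(1, max_components + 1):
        if d.size < 10 * k:
            underpowered = True  # sample too small for this candidate
            continue
        try:
            fit = fit_log_exponential(
                d, n_components=k, seed=seed, n_bootstrap=0, truncation_s=truncation_s
            )
        except FitError:
            continue  # collapse favors the simpler model; not low confidence
        bics[k] = fit.bic
    if not bics:
        raise FitError(f"no component count between 1 and {max_components} is fittable")
    best = min(sorted(bics), key=lambda k: (round(bics[k], 9), k))
    return ModelChoice(n_components=best, low_confidence=underpowered, bic=bics)


# ---------------------------------------------------------------------------
# Gaussian residual-current fit
# ---------------------------------------------------------------------------

@dataclass
class ResidualFit:
    """Gaussian (mixture) model of a residual-current histogram.

    ``components`` are (mean_pa, sd_pa, weight) sorted by mean ascending;
    ``uncertainties`` are per-mean bootstrap SEs.
    """

    n_components: int
    components: list[tuple[float, float, float]]
    uncertainties: list[float]
    log_likelihood: float
    n_obs: int

    @property
    def means_pa(self) -> list[float]:
        return [m for m, _, _ in self.components]

    @property
    def sds_pa(self) -> list[float]:
        return [s for _, s, _ in self.components]

    @property
    def weights(self) -> list[float]:
        return [w for _, _, w in self.components]


def _fit_gauss_once(x: np.ndarray, k: int, seed: int | None) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    means0 = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    var0 = max(float(x.var()) / k, 1e-12)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        means_init=means0,
        weights_init=np.full(k, 1.0 / k),
        precisions_init=np.full((k, 1, 1), 1.0 / var0),
        max_iter=500,
        tol=1e-8,
        reg_covar=1e-10,
        random_state=seed,
    ).fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise FitError(f"Gaussian mixture EM did not converge for {k} components")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(k))
    if np.any(sds < 1e-6):
        raise FitError("singular Gaussian component (sd -> 0)")
    order = np.argsort(means)
    ll = float(gm.score(x.reshape(-1, 1)) * x.size)
    return means[order], sds[order], gm.weights_[order], ll


def fit_gaussian_residual(
    residuals: Sequence[float],
    n_components: int = 1,
    seed: int | None = None,
    n_bootstrap: int = 200,
) -> ResidualFit:
    """Gaussian-mixture ML fit of residual currents with bootstrap SEs."""
    x = np.asarray(residuals, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("residual currents must be finite")
    if x.size < 10 * n_components:
        raise FitError(
            f"need at least {10 * n_components} residuals for {n_components} "
            f"component(s); got {x.size}"
        )
    if np.ptp(x) == 0:
        raise FitError("all residual currents identical; zero-variance input")
    means, sds, weights, ll = _fit_gauss_once(x, n_components, seed)
    ses = [float("nan")] * n_components
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        means_bs = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, x.size, size=x.size)
            try:
                mb, _, _, _ = _fit_gauss_once(x[idx], n_components, seed)
            except FitError:
                continue
            means_bs.append(mb)
        if len(means_bs) >= max(20, n_bootstrap // 2):
            ses = list(np.std(np.array(means_bs), axis=0, ddof=1))
    return ResidualFit(
        n_components=n_components,
        components=[
            (float(m), float(s), float(w)) for m, s, w in zip(means, sds, weights)
        ],
        uncertainties=[float(s) for s in ses],
        log_likelihood=ll,
        n_obs=int(x.size),
    )
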