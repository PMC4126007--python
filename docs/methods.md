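# Methods

## Physical picture and model

A single α-hemolysin pore in a lipid bilayer passes an open-pore current
I₀ under constant voltage. DNA entering the pore blocks the current to a
species-specific residual level until it translocates or the duplex
dissociates. The analysis treats a recording as a renewal process:
blockade events with Poisson arrivals (per event class), exponential (or
exponential-mixture) dwell times, and Gaussian current noise around
piecewise-constant levels.

Three event classes are distinguished, following the standard dwell-time
rules for these experiments: spike-like ssDNA translocations (≤1 ms),
rectangular ssDNA blocks (1–10 ms), and duplex captures (>10 ms). Duplex
events may end with a brief deeper "ending spike", the signature of
strand dissociation and translocation through the constriction.

### Equilibrium estimator

For a symmetric mixture of two complementary strands, each loaded at
S = [ssDNA]₀,total/2, the measured quantities are the total ssDNA block
frequency f_ss (s⁻¹) and the per-strand capture rates k_on (µM⁻¹ s⁻¹,
block frequency normalized by concentration; the two strands' rates are
averaged). Since block frequency is proportional to free ssDNA
concentration, c = f_ss/(2 k_on) estimates each strand's free
concentration, and mass action gives

    Kd = c² / (S − c)        [µM].

This is algebraically the block-frequency form
Kd = (f_ss/k_on)²/2([ssDNA]₀ − f_ss/k_on) when [ssDNA]₀ denotes the
*total* ssDNA (both strands); that reading reproduces the per-replicate
Kd table of the reference system, whereas the per-strand reading does
not. `implied_fss` inverts the estimator through the positive root of
c² + Kd·c − S·Kd = 0 and is used as an independent closure oracle in the
tests. The estimator is strictly increasing in f_ss on its domain
0 < c < S.

Ligand-induced duplex stabilization is expressed as
ΔE = R·T·ln(τ_after/τ_before) with R = 8.314 J mol⁻¹ K⁻¹ and
T = 295.15 K by default (recordings at 22 ± 1 °C). Note that for the
packaged reference system this formula evaluated at the fitted dwell
peaks gives 4.60 kJ/mol (C-C, 59 → 384 ms) and 0.71 kJ/mol (mC-C,
69 → 92 ms); the values 3.8 ± 0.5 and 0.53 ± 0.07 kJ/mol reported
alongside those peaks in the original account of this system do not
follow from R·T·ln of the printed peak ratios — which dwell summaries
entered that calculation is not stated there. The formula here is
implemented exactly as written and the discrepancy is left visible
rather than reconciled.

Two further arithmetic inconsistencies in the reference measurement
table are preserved rather than patched: the probe-strand mean capture
rate is quoted as 3.49 µM⁻¹ s⁻¹ while its six replicates average 3.44,
and two quoted standard deviations (0.19 for both the target capture
rate and the +Ag⁺ block frequency) differ in the last digit from the
sample SDs of the quoted replicates (0.18, 0.20). `build_table2`
recomputes all aggregates from the replicates; the reported strand means
can be supplied explicitly (`kon_strand_means`) when reproducing the
original per-replicate Kd values, two of which (0.039 and 0.045) also
differ by one unit in the last digit from what any single averaged
capture rate yields (0.038, 0.046).

## Event detection

* **Baseline.** The open-pore level is anchored at the 0.999 sample
  quantile, thresholded at `threshold_fraction` (default 0.5) of that
  anchor, and refined as the median of above-threshold samples with a
  scaled-MAD noise SD. This is insensitive to blocked duty cycles up to
  ~50%; a mostly-blocked trace, or one without a contiguous open stretch
  of `baseline_window_s` (default 0.1 s), raises a diagnostic error. A
  trace blocked at a *constant* level for its entire duration is
  indistinguishable from an open pore at that level; this limitation is
  inherent to baseline-free detection.
* **Segmentation.** Events are maximal below-threshold runs, with a
  2-sample debounce (sub-debounce returns to baseline do not split an
  event), a 2-sample minimum length, and boundary-touching events
  dropped. Entry and exit use the same threshold; 50% of baseline
  separates the ~37–42 pA duplex residual levels from a ~150 pA open
  pore unambiguously.
* **Residual current.** Mean over the blocked plateau, excluding the
  terminal spike and trimming `edge_trim_samples` (default 2) at each
  plateau edge to exclude filter-smeared transition samples. Without the
  trim the 5 kHz Bessel smear biases residuals by ~0.2 pA at the default
  conditions.
* **Ending spike.** A trailing run of ≥2 samples at least
  `spike_k_sd × noise SD` (default k = 5) below the plateau median,
  allowed to stop up to 3 samples short of the event end (the low-pass
  filter smears the spike-to-open transition). The spike is excluded
  from the residual mean but included in the dwell. The qualitative
  notion of an "ending spike" in the source experiments is
  operationalized by exactly this k·SD rule.
* **t_on.** Defined end-of-previous-event to start-of-next (inter-event
  interval); NaN for the first event.

## Distribution fitting

Dwell times are fitted by maximum likelihood on the raw dwells — not
least squares on binned counts — because the exponential-mixture MLE is
bin-width independent; the log-time histogram (default 10 bins/decade)
is a display device. The log-time density of a single exponential peaks
exactly at t = τ, an identity the fit satisfies by construction and the
tests verify numerically.

Mixtures use EM with deterministic quantile initialization; component
collapse (vanishing weight, or tau ratio < 1.02) raises an error, which
the BIC-based `model_selection` treats as evidence for the simpler
model. Ties favor fewer components; samples too small for a candidate
count (n < 10k) flag the choice low-confidence.

**Left truncation.** Duplex-only fits exclude events ≤ 10 ms, mirroring
the standard pre-filter for duplex dwell analysis. Fitting an
untruncated mixture to truncated data is misspecified and biases both
taus upward substantially at realistic event counts; by memorylessness
each exponential component is again exponential in t − t₀ beyond the
truncation point, so the pipeline fits the shifted dwells
(`truncation_s`), which is unbiased for the taus. The reported weights
are then component fractions within the truncated regime.

Residual-current histograms are fitted with scikit-learn's Gaussian
mixture EM (quantile-initialized means, deterministic), guarding against
singular components. All peak uncertainties are nonparametric bootstrap
SEs (200 seeded resamples by default; resamples whose fit collapses are
skipped, and SEs are reported NaN if fewer than half survive).

## Simulator

The generator is the package's ground-truth instrument; its defaults are
the study conditions of the reference system: 20 kHz sampling, 4-pole
low-pass Bessel filter at 5 kHz (bilinear digital design, applied
causally as in an acquisition amplifier), 150 mV holding potential
(metadata), Gaussian noise SD 2 pA, open-pore current 150 pA. The open
level is not printed in the reference account; 150 pA is the typical
α-HL open current at this voltage and salt. Residual levels and dwell
peaks per condition come from the fitted peaks of the reference system
(e.g. C-C: 59 ms at 41.5 pA; with Ag⁺: 51/384 ms at 36.8 pA; ssDNA:
17.4 pA). The 0.3/0.7 split between the two stabilized-duplex dwell
components is a modelling choice — only the peak positions are reported
— as is the even spike/rectangular split of the total ssDNA rate.

Arrivals are homogeneous Poisson per class; a single pore holds one
molecule at a time, so later arrivals are deferred until 0.5 ms after
the previous block ends (single-occupancy queue). Configurations whose
expected duty cycle exceeds 0.5 are rejected — the baseline would no
longer be estimable. ssDNA dwells are drawn from exponentials truncated
to their class windows (0.15–0.9 ms, 1.2–9.5 ms) so generated labels are
consistent with the classification rules and sit clear of the class
boundaries; duplex dwells are untruncated exponential mixtures so dwell
fitting is unbiased, and the sub-10 ms tail of a duplex component is
excluded by the same >10 ms rule as in the real analysis. The ending
spike is a rectangular sub-block (default 1 ms wide, dropping to 50% of
the residual level); its true shape is visible but unparameterized in
the source recordings.

What the simulator does **not** emulate: baseline drift, capacitive
transients and 1/f noise, multi-level blocks, voltage-dependent capture,
vendor acquisition formats, or inter-pore variability. Passing tests
therefore demonstrate correctness of the estimators under the stated
stochastic model, not robustness to every artifact of bench recordings.

## Problem sizes and numerical choices

Tests and the demo use recordings of 30–600 s and fitted samples of
10³–5·10³ dwells/residuals, sizes at which parameter-recovery checks
resolve 3-SE agreement comfortably. Statistical assertions use frozen
seeds and 3-SE tolerances; the Kd closure check uses 50 Poisson
replicates of a 500 s recording and requires the median estimate within
10% of truth. EM converges on a relative log-likelihood change of 1e-10
(max 1000 iterations); the quadratic inversion oracle agrees with the
estimator to 1e-10 relative error. Presentation rounding uses half-up
decimal rounding (`round_display`) so that e.g. a mean of exactly 6.515
displays as 6.52 despite its float image; all internal arithmetic is
double precision.

## Known limitations

* Exponential-mixture components closer than ~2× in tau are weakly
  identifiable at realistic event counts; `model_selection` will
  typically (and correctly, by BIC) prefer one component.
* Dwell measurement under the causal Bessel filter carries a group
  delay of a few samples at both edges; it largely cancels in t_off but
  not in absolute event timestamps.
* The residual of very short (≤4 sample) events is dominated by smeared
  transition samples; residual-current analysis is intended for the
  duplex class.
* `estimate_baseline` cannot detect a recording that is blocked at a
  constant level for its whole duration (see above).
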