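# porekinetics

Analysis of α-hemolysin (α-HL) single-channel recordings of DNA-duplex
capture: simulation of current traces, blockade-event detection and
classification, dwell-time and residual-current distribution fitting, and
estimation of duplex hybridization equilibria from block statistics.

## The problem

When a single DNA molecule enters an α-HL pore held under voltage, the
ionic current drops from the open-pore level to a molecule-specific
residual level until the molecule translocates or dissociates. In a
mixture of two complementary strands, short blocks (<10 ms) report
unhybridized ssDNA while long blocks (>10 ms) report captured duplexes.
This package implements the event-level statistics that turn such
recordings into chemistry:

* **Event detection** — blocks are maximal intervals below a fixed
  fraction (default 50%) of the open-pore baseline, classified by dwell
  time `t_off` (≤1 ms spike-like ssDNA, 1–10 ms rectangular ssDNA,
  >10 ms duplex), with the residual current taken over the blocked
  plateau excluding the terminal dissociation spike.
* **Distribution fitting** — dwell times are fitted as exponential
  mixtures by maximum likelihood, displayed on the log-time axis where
  the density `f(log t) = Σ wᵢ (t/τᵢ) e^{−t/τᵢ} ln10` peaks exactly at
  `t = τᵢ`; residual-current histograms are fitted as Gaussian mixtures.
  Peak standard errors come from a seeded nonparametric bootstrap.
* **Equilibrium estimation** — with `f_ss` the total ssDNA block
  frequency in a symmetric 1:1 strand mixture and `k_on` the averaged
  single-strand capture rate (block frequency per µM), the free
  concentration of each strand is `c = f_ss / (2 k_on)` and

      Kd = c² / (S − c),   S = [ssDNA]₀,total / 2,

  equivalently `Kd = (f_ss/k_on)² / 2([ssDNA]₀ − f_ss/k_on)` with
  `[ssDNA]₀` the total ssDNA of both strands. Ligand-induced
  stabilization is summarized as the dwell-ratio energy shift
  `ΔE = R·T·ln(τ_after/τ_before)` and as residual-current differences
  with root-sum-square propagated errors.
* **Simulation** — a seeded generator renders recordings with the same
  statistical structure (Poisson arrivals, exponential dwell mixtures,
  species-specific residual levels, ending spikes, 20 kHz sampling,
  4-pole Bessel low-pass at 5 kHz), so every stage is testable against
  known ground truth.

The package ships the measured capture-rate and block-frequency
replicates for a 16-nt probe/target system carrying a single C-C
mismatch, whose duplex is strongly stabilized by Ag⁺ through C-Ag⁺-C
metallo-base-pair formation (`porekinetics.CC_MIXTURE_MEASUREMENTS`).

## Worked example

Run the packaged demo — a 600 s simulated recording of the C-C duplex
with the stabilizing ion (two-component dwell mixture at 51/384 ms,
residual level 36.8 pA), detected, fitted, and combined with the
packaged equilibrium measurements:

```sh
$ porekinetics demo --outdir demo_out --seed 0
dwell peaks: 49 ms, 398 ms
report written to demo_out
```

The two fitted dwell peaks recover the simulated 51 ms and 384 ms
components within their bootstrap uncertainties. `demo_out/` contains
the event table, fit JSONs, the equilibrium table and a run manifest
(seed, config hash, package version); reruns with the same seed are
bit-identical.

The equilibrium table built from the packaged replicate measurements:

```python
>>> import porekinetics as pk
>>> print(pk.reference_equilibrium_table().to_frame().round(3).to_string())
      kon_target_c_um_s  kon_probe_um_s  fss_no_ag_hz  fss_with_ag_hz  kd_no_ag_um  kd_with_ag_um
rep1              3.600           3.310         6.210           3.810        0.105          0.038
rep2              3.410           3.780         6.250           4.200        0.107          0.046
rep3              3.730           3.330         6.570           4.230        0.119          0.047
rep4              3.880           3.360         7.030           4.170        0.137          0.046
rep5              3.800           3.020           NaN             NaN          NaN            NaN
rep6              NaN             3.840           NaN             NaN          NaN            NaN
mean              3.684           3.440         6.515           4.102        0.117          0.044
sd                0.184           0.312         0.379           0.197        0.015          0.004
```

Adding Ag⁺ drops the ssDNA block frequency from 6.52 ± 0.38 s⁻¹ to
4.10 ± 0.19 s⁻¹, i.e. the dissociation constant falls from
~0.12 µM to ~0.04 µM — the ion shifts the hybridization equilibrium
toward the duplex. The corresponding dwell-ratio energy shift:

```sh
$ porekinetics energy --tau-before 0.059 --tau-after 0.384
delta_E = 4.596 kJ/mol (4596.4 J/mol)
```

Other CLI verbs: `simulate`, `detect`, `fit`, `kd`, `report` (see
`porekinetics --help`); everything is equally available as library
functions (`sample_event_train`, `detect_events`, `fit_log_exponential`,
`estimate_kd`, `build_table2`, …).

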