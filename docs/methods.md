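# Methods

`tmstheta` implements a TMS-EEG time-frequency analysis for regional theta
differentiation — the observation that in healthy controls the theta-band
response to single-pulse TMS depends on which cortical site (lDLPFC, lPPC,
DMPFC) is stimulated, whereas in the clinical high-risk state for psychosis
(CHR-P) this differentiation is flattened. Because no recordings are
distributed with the package, every statistical claim is validated on
synthetic cohorts whose generative structure is documented here.

## Time-frequency decomposition

Epoched data (µV, epoch × channel × sample, times in ms relative to the
pulse) pass through:

1. **Pulse-window interpolation.** Samples strictly inside (−1, 15) ms are
   replaced per channel and trial by the line through the boundary samples.
   This removes residual decay artifacts confined to the window and is the
   identity on data already linear there.
2. **Zero-phase band-pass, 3–100 Hz.** Cascaded order-6 Butterworth
   high-pass (cutoff 0.8·3 Hz) and low-pass (1.1·100 Hz) sections applied
   forward–backward. The normative contract — gain within 5% over
   [1.25·lo, 0.8·hi], ≥ 20 dB attenuation at 0.5·lo and 1.5·hi, zero
   group delay — is tested directly; the filter family is an implementation
   detail. Cutoff margins (0.8×, 1.1×) were chosen from the closed-form
   Butterworth magnitude response so that the forward–backward squared
   response meets both the passband and stopband constraints.
3. **Morlet convolution.** Thirty analysis frequencies
   f_k = 3·(80/3)^((k−1)/29) Hz paired with cycle counts
   c_k = 3·(10/3)^((k−1)/29) — geometric progressions are the only
   parameter-free reading of "logarithmically increasing in 30 steps".
   Each epoch and channel is convolved ('same' alignment) with a zero-mean
   complex Morlet wavelet (σ_t = c/(2πf), support ±5σ_t); **power is
   averaged across epochs** (trial-average of power, not power of the trial
   average), so non-phase-locked activity is retained. This choice is
   forced by internal consistency: the induced-activity control (ERP
   subtracted from every trial before decomposition) is only meaningful if
   the total response contains induced power. The convolution runs in
   single-precision FFTs; power maps are subsequently dB-normalized, so the
   ~1e−6 relative error is irrelevant.
4. **Decibel baseline normalization.** dB(f,t) = 10·log10(P(f,t)/B(f)) with
   B(f) the mean power over −400 to −200 ms, separately per frequency,
   channel, and dataset (subject × site). By construction the baseline
   window's mean *linear ratio* is exactly 1 at every frequency.
5. **20-ms temporal binning**, anchored at the epoch start, arithmetic mean
   per bin, trailing partial bin dropped, bin centers as timestamps.
   Normalization precedes binning; the reverse order differs (Jensen) and a
   regression test pins the implemented order.

Edge handling: cells within half the nominal wavelet duration (c/f/2) of an
epoch edge are flagged; with the default ±1000 ms epochs no flagged bin
touches the analysis windows (theta 60–300 ms, gamma 20–100 ms, baseline
−400…−200 ms). The epoch length itself is a package choice (the protocol
does not fix one): ±1000 ms is the shortest symmetric window that
accommodates the 3 Hz / 3-cycle wavelet plus the baseline.

## Regions of interest

Theta: 4–7.5 Hz, 60–300 ms, fixed fronto-central electrodes FC1, FCz, FC2,
C1, Cz, C2. Gamma: 30–45 Hz, 20–100 ms, one electrode per stimulation site
selected by maximal in-window mean dB power (ties broken by montage order).
Band membership uses closed frequency intervals on the grid and half-open
time intervals [t_lo, t_hi) keyed by bin center — a convention the analysis
needs but that is otherwise arbitrary; it is configurable. These bands
hard-code the outcome of a visual-inspection step that cannot itself be
implemented.

## Permutation testing

**Within group.** Per subject, each site's ROI map is centered against the
subject's across-site mean (the three deviation maps sum to zero). For one
site, the null flips the sign of each subject's whole deviation map
independently (5000 permutations by default) and

    z(f,t) = (observed mean − mean of permuted means) / std of permuted means

with the n−1 std denominator. Cells with zero permutation variance get
z = 0 with a warning. Cluster correction: two-sided cluster-forming
threshold |z| ≥ Φ⁻¹(1 − 0.05/2) = 1.96, 8-connected components in the
frequency × time plane, and removal of clusters whose size (in bins) does
not exceed the 97.5th percentile of the per-permutation maximum cluster
sizes. The null max-size distribution is built from the same permutations
as the z-map (single pass), pooling positive and negative suprathreshold
cells in one mask; surviving clusters are reported with their signed peak
(dB, Hz, ms, z, and a two-sided normal p for the peak z). Sidedness, the
pooling of signs, and the normal peak-p mapping are package choices where
the procedure leaves them open.

**Between groups.** Both groups are subject-centered first; the statistic
is the group-A minus group-B mean deviation map, the null reassigns
subjects to groups uniformly preserving group sizes, and the identical
z-scoring and cluster correction apply.

**Exact oracles.** For small n, `signflip_zmap_exact` enumerates all 2ⁿ
sign patterns and `between_group_zmap_exact` all label splits. The
enumerations hold the *complete* null population, so they use the
population (ddof = 0) std; the Monte-Carlo estimator keeps ddof = 1 and
converges to the enumeration as permutations grow — the test suite checks
agreement within three delta-method standard errors, using the exact null's
skewness and kurtosis where it is far from Gaussian (20 atoms for 3+3
splits).

Each site is tested independently with its own RNG stream spawned from the
single seed, so results do not depend on site order.

## Band-power statistics

Band power is the scalar mean dB over band frequencies, window bins, and
the electrode set, per subject × site. The group analysis fits

    mean_power ~ group * site + age + antipsychotic + (1 | subject)

by REML (statsmodels MixedLM), reference levels HC and lDLPFC. Wald t
statistics use residual degrees of freedom (n_obs − n_fixed); Satterthwaite
approximations are not available in the backend, and the summary records
`df_method = "residual"`. Conditional R² follows Nakagawa:
(var_fixed + var_subject) / (var_fixed + var_subject + var_resid). A
constant response short-circuits to zero coefficients with an undefined,
flagged R²; covariates that are constant in the fitted subset (e.g. no
medicated subject) are dropped rather than allowed to make the design
singular. The comorbidity variant replaces group by a mood-comorbidity
indicator within the CHR-P rows.

Clinical associations are Spearman rank correlations (average ranks for
ties, pairwise deletion of missing values) between band power per site and
each clinical item, with Benjamini–Hochberg correction. The default
correction family is all site × item tests within one band (3 × 11 = 33
tests per band, applied separately for theta and gamma); `band_site` and
`global` families are available because the original family definition is
ambiguous. Pairs with fewer than three complete observations yield an
undefined ρ and are excluded from the family.

## Synthetic cohorts

Each subject × site EpochSet is a sum of

- **1/f background noise**, synthesized in the frequency domain with
  amplitude ∝ f^(−α/2) (α = 1 by default) and an analytically calibrated
  RMS of 10 µV; the log-log Welch slope reproduces −α within ±0.3 over
  4–80 Hz.
- **A phase-locked ERP**: an N100/P200-like biphasic waveform (Gaussians at
  100 and 200 ms, 5 µV), identical across trials.
- **A theta burst**: Gaussian-windowed 5.5 Hz sinusoid centered at 180 ms
  with 240 ms duration (σ = duration/6, so the support matches the 60–300
  ms window), random uniform phase per trial — the theta response is
  therefore almost entirely induced, which lets the induced-activity
  control be exercised.
- **A gamma burst**: 38 Hz, centered 60 ms, 80 ms duration, topography
  peaked at C1 (lDLPFC, lPPC) or Cz (DMPFC) so the peak-electrode selector
  has something to find.

Topographies fall off as cos(π/2 · d/r) with scalp distance d from the
center electrode (FCz for theta/ERP) and r = 9 cm, zero beyond r —
qualitatively fronto-central without modelling volume conduction.

**Amplitude calibration.** Burst amplitudes are specified in dB
operationally: the injected power is scaled so that the analytic expected
dB map, 10·log10(1 + A²w²P_burst(f,t)/P_noise(f)), averaged over the
band's grid frequencies, time window, and electrode set, equals the
requested value. P_noise(f) is computed in closed form from the synthesis
spectrum, the squared forward–backward filter response, and the wavelet's
power transfer summed over the full DFT circle (the analytic wavelet is
one-sided, so positive- and negative-frequency bins contribute unequally —
treating them symmetrically overstates the noise floor by 3 dB and was the
largest defect caught by the recovery oracle during development).
P_burst is the Morlet power of the band-passed unit burst, averaged over
four carrier phases. The scalar scale is solved by bisection per subject.
Recovery tests confirm the pipeline reads back injected targets with ≈0.05
dB bias and ρ > 0.9 against the stored per-subject targets at 100 epochs.

**Effect structure.** Default theta targets: HC lDLPFC 3.0, lPPC 1.6,
DMPFC 1.4 dB; CHR-P flat at 2.9 dB. These are *not* reported estimates —
the study publishes deviations, not generative amplitudes — but place the
simulated deviation maps (≈ +1.0/−0.4/−0.6 dB for HC, 0 for CHR-P) in the
visually reported 0.5–3 dB range with the reported ordering, and the CHR-P
level near the HC lDLPFC response. A subject-level random effect
(SD 0.5 dB, shared across sites) adds between-subject variability; gamma
targets are 1 dB everywhere (no group or site differences). Clinical items
are drawn around group base rates (CHR-P means near published cohort
values, HC near zero, negative-symptom items missing for HC and
occasionally for CHR-P) plus an item-specific slope times the subject's
theta deviation (defaults: −0.8 to −1.0 points/dB on P1, N2, N4, N6),
then rounded and clipped to 0–6.

Reproducibility: every subject × site stream is seeded from
SeedSequence(seed, spawn_key=(1, i, j)), so outputs are bit-identical
regardless of generation order or subject subsetting.

**What the generator does not emulate:** volume conduction and channel
covariance, TMS decay/muscle/blink artifacts, heteroscedastic or
non-Gaussian noise, recording drift, evoked latency jitter, site-dependent
auditory confounds. Passing tests therefore demonstrate correctness of the
*analysis* under the stated generative assumptions, not robustness to real
recording pathology (artifact cleaning is upstream of this package's
scope).

## Desk-scale study conditions

Validation experiments shrink the cohort, not the method: 500 Hz sampling,
the six ROI electrodes as the montage, 20 epochs per site (10 for the
null-calibration cohorts, where the test's error rate is pivotal in the
epoch count), a 15-frequency grid, the 0–400 ms window (20 bins), and 500
permutations. Under these conditions:

- **Family-wise error:** across 200 null cohorts (all effects zero, so
  sites are exchangeable by construction), the within-group test reports a
  significant cluster in ≤ 5% of the 600 (cohort, site) analyses.
- **Pattern recovery:** with default effects, 25 replicate cohorts (20
  HC-like + 20 CHR-like) recover the qualitative findings — theta-window
  clusters at all three sites with signs +/−/− in HC, no clusters in
  CHR-P, and a between-group lDLPFC cluster — each in ≥ 80% of replicates.
- **Mixed-model coverage:** tables drawn directly from the generating
  linear mixed model (β_site = −1.0, β_interaction = +0.8, subject and
  residual SD 0.5, n = 50/group) put the truth inside the 95% CI in ≥ 90%
  of 100 replicates.

`scripts/acceptance.py` recomputes the family-wise error rate from scratch
at exactly these conditions.

## Numerical notes and limitations

- Tie-break for the gamma electrode: first maximum in montage order.
- The cluster-size percentile uses linear interpolation on integer sizes;
  significance requires size strictly greater than the threshold.
- MixedLM occasionally converges to a variance boundary on tiny cohorts;
  the summary flags singular fits instead of failing.
- Gamma-band permutation testing is intentionally absent (the transient
  gamma cluster biases size-based correction); beta-band analysis is out of
  scope.
- The BrainVision reader epochs around stimulus markers but performs no
  artifact cleaning; real data must be cleaned upstream.
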