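# Methods

## The model

`oscipat` treats EEG as a superposition of transient oscillatory events
over slow background activity and quantifies those events directly,
without sleep staging. The analysis chain is deterministic:

1. **Morlet CWT.** `W(s, t₀) = s^(−1/2) ∫ x(t) ψ*((t−t₀)/s) dt` with
   `ψ(t) = π^(−1/4) exp(iω₀t) exp(−t²/2)` and ω₀ = 2π, so that scale and
   Fourier frequency satisfy s ≈ 1/f (the exact modulus ridge of a
   sinusoid at frequency f lies at `s = (ω₀ + √(ω₀²+2)) / (4πf)`,
   ≈ 1.24% above 1/f; the package accounts for this where it matters).
   An alternative 1/s prefactor is available (`cwt_norm="linear"`); it
   rescales each scale row by a constant and cannot change skeletons,
   pattern sets or band statistics.
2. **Skeleton.** Per time step, the k = 7 largest across-scale *local*
   maxima of |W| (strictly greater than both scale neighbours; plateaus
   count once at their lowest-scale index; grid-boundary scales are
   excluded; cells inside the cone of influence are excluded). A
   `skeleton_mode="topk"` variant takes the k largest values without the
   local-maximum requirement, for sensitivity analyses.
3. **Linking.** Points in consecutive time steps whose scales differ by
   ≤ δs = 0.0008 s belong to one pattern. When several candidates
   compete, heads are served in descending modulus and claim the
   nearest unclaimed scale (ties toward the lower scale) — a
   deterministic completion of the proximity rule. Fundamental frequency
   is `Fm = mean(1/sᵢ)`; duration `T = t_end − t_start`; patterns with
   `T < 1/Fm` are noise and dropped (the boundary `T = 1/Fm` is kept).
4. **Band statistics.** Fm bins each retained pattern into twenty bands
   Δf₁ [1;2], Δf₂ [2;4], …, Δf₂₀ [38;40] Hz under the half-open
   convention `[low, high)` with a closed top edge at 40 Hz — the only
   overlap-free reading of shared band endpoints. Counts are normalized
   per 30-s epoch; a pattern belongs to the epoch containing its start
   (boundary ties to the later epoch); a final partial epoch is dropped
   to avoid downward bias. Patterns with Fm outside [1, 40] Hz go to an
   overflow bucket for audit, so per-band counts plus overflow always
   equal the retained total.
5. **Group comparison.** Inference uses one number per subject per
   channel × band cell (no epoch-level pseudo-replication). The
   two-sided Mann–Whitney U test uses the exact null distribution
   (counting recurrence) for combined samples ≤ 30 without ties and the
   tie-corrected, continuity-corrected normal approximation otherwise;
   the two-sided p is `2·min(P(U≤u), P(U≥u))`, capped at 1. Cells with
   p ≤ α = 0.001 are flagged; no multiple-testing adjustment is applied
   by default (a Benjamini–Hochberg option exists) so the raw-α
   procedure of the underlying study design is reproduced. Percent
   difference is `100·(mean_A − mean_B)/mean_A`, group A being the
   reference group.

## Key parameters

| parameter | default | meaning / why |
|---|---|---|
| `freq_min, freq_max` | 1, 40 Hz | analysis range; sampling must satisfy Nyquist (≥ 80 Hz) |
| `n_scales` | 117 | log grid, ~22 voices/octave. This is the finest log grid whose adjacent-scale gap exceeds δs everywhere (so a link can only join identical grid scales and linking is unambiguous), and it gives every 2-Hz band at least two grid frequencies, so one-bin ridge jitter cannot change a pattern's band. One guard scale beyond each end keeps edge-of-range ridges interior (the high guard sits two ratio steps up to preserve the minimum gap). |
| `omega0` | 2π | scale ↔ frequency identification |
| `skeleton_k` | 7 | skeleton width per time step |
| `delta_s` | 0.0008 s | absolute scale-proximity threshold per time step |
| `epoch_seconds` | 30 | count-normalization window |
| `alpha` | 0.001 | significance level |
| `band_pass`, `notch_hz` | off | optional pre-filters; raw referenced EEG is analyzed by default |
| `block_seconds` | 600 | records longer than this are transformed in overlapping blocks |

## Numerical choices

* The transform is computed by frequency-domain multiplication with the
  analytic Morlet spectrum, padded past the slow-scale wavelet support;
  this equals direct quadrature of the transform integral to ~1e-13
  relative (asserted at 1e-6 in tests).
* **Modulus floor.** Skeleton candidates below 1e-9 of the frame's
  maximum modulus are discarded: double-precision FFT rounding leaves
  ripple at ~1e-12–1e-11 of the dominant component which would otherwise
  form spurious ridges (e.g. "patterns" at 1 Hz in a pure 10-Hz
  sinusoid).
* **Near-floor chaos.** Deterministic but very weak ridges (relative
  modulus below ~1e-6, from spectral tails and burst interference) have
  almost-flat across-scale maxima; a 1e-16-level change in the input
  (different FFT length, one added sample) can flip their bin and hence
  their chain structure. Strong patterns are bit-stable; tests of
  blocked-vs-whole equality and burst-injection monotonicity therefore
  assert exact equality on strong patterns and tolerate a few ripple
  patterns elsewhere.
* **Block processing.** Long records are transformed in blocks whose
  context extends eight slow-scale lengths past the core (Gaussian
  envelope ⇒ truncation far below rounding in the core); the cone of
  influence is always evaluated against the whole record, and linking
  runs once on the concatenated skeleton.
* Ties: equal-modulus skeleton points order toward the lower scale;
  plateau maxima take the lowest-scale index; linking ties break toward
  the lower scale. All choices are deterministic across platforms.

## The synthetic cohort

Patient recordings cannot be shipped, so validation uses a generator
whose statistical structure matches what the pipeline assumes:

* **Background**: Gaussian noise with a 1/f^`exponent` spectrum whose
  stochastic content is confined below `background_cutoff_hz` (default
  0.5 Hz) — activity dominated by slow waves. Rationale: a *full-band*
  stochastic background turns out to saturate the skeleton with an
  amplitude-independent floor of ~20 retained "patterns" per band per
  30 s (local maxima do not care how weak the noise is), which both
  swamps event-rate ground truth and couples bands through competition
  for the k = 7 slots. With the sub-band background, in-band ridges come
  almost exclusively from injected events and detected counts stay
  aligned with the configured truth. The full-band power law remains
  available (`background_cutoff_hz=None`) as a stress test.
* **Bursts**: one class per analysis band (EEG carries activity across
  the spectrum, and a class in every band keeps spectral leakage from a
  contrasted band diluted by its neighbour's own stable content).
  Carriers are placed so the wavelet ridge falls at each band's
  geometric centre (carrier = 1.0124 × centre), maximizing the margin to
  both band edges; the 2–8 Hz carriers are additionally spread so the
  centroid of two co-active neighbouring bursts avoids band edges.
  Durations are several carrier cycles (long at low frequencies to keep
  the spectral skirt inside a 2-Hz band); amplitudes default to 4× the
  background RMS with a raised-cosine (Tukey/Hann) envelope; burst
  counts are Poisson; durations are lognormal truncated at two periods.
* **Group effects**: group B burst rates are scaled by
  `1 − rate_effects[band]` — default 20% in Δf₂–Δf₄, 60% in Δf₁₉, 75%
  in Δf₂₀, emulating a patient-vs-control contrast concentrated in
  delta/theta and low gamma. Duration effects are available separately.
* **Between-subject variability**: gamma multipliers with CV 0.02 per
  subject × band (shared across channels) plus an independent CV 0.03
  per channel. These small values are deliberate: a 20% rate contrast
  that reaches p ≤ 0.001 at n = 14 per group — the sensitivity the
  method is designed around — implies subject-level variability of only
  a few percent in the underlying cohorts.
* **Determinism**: every record is a pure function of
  (seed, group, subject, channel) through integer-keyed RNG streams, so
  cohorts reproduce byte-exactly without storage.

### What the surrogate does not emulate

Sleep-stage architecture, artifacts (EMG/EOG, electrode pops), the
broadband in-band stochastic floor of real EEG (available only via the
stress-test background), inter-channel correlation of the signal
itself, and non-stationarity across the night. Passing the recovery
tests therefore demonstrates that the pipeline measures event-rate
contrasts correctly under its own model of the data — not that real
recordings are free of the floor and leakage effects discussed below.

## Validation sizes and known limitations

The recovery study runs at desk scale: 360-s records (12 epochs) at
200 Hz, 4 channels, 14 subjects per group, 10 seeds (the acceptance
script uses 480-s records for its single-seed study). A full-overnight
run only changes `record_length`.

Two limitations of the method itself, measured with the synthetic
cohorts and worth knowing before interpreting real-data results:

* **Leakage-limited specificity.** The Morlet at ω₀ = 2π has a spectral
  width σ(ln f) ≈ 16%, while the 2-Hz bands above 30 Hz are only ~5-6%
  wide: adjacent high bands are far inside one resolution cell. A strong
  rate contrast in one band therefore produces systematic few-percent
  count changes in neighbouring bands (flank suppression of weak maxima,
  merging of co-active events, competition for the 7 skeleton slots).
  With n = 14 these couplings sit near the p ≤ 0.001 detection edge: the
  strongest contrasted bands are flagged reliably, but exact band-level
  specificity of the flag set is not attainable — neighbouring bands can
  flag spuriously, and a 20% contrast in a leak-diluted band may miss
  the threshold. The measured percent reductions remain close to truth
  (gamma contrasts within a few points; low-band contrasts attenuated to
  roughly half by leak-in from unperturbed neighbours).
* **Count dilution under a broadband floor.** With the stress-test
  full-band background, all bands carry a large common count floor;
  relative group differences are then strongly attenuated. Real EEG sits
  between the two background models, so absolute percent differences on
  real data should be interpreted as lower bounds on the underlying
  event-rate contrast.
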