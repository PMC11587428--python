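# oscipat — oscillatory wavelet-pattern analysis of sleep EEG

`oscipat` quantifies transient oscillatory events ("patterns") in
whole-night EEG and compares their per-band rates and durations between
two subject groups. It is aimed at sleep/EEG researchers who want a
stage-free description of nocturnal brain activity: the whole recording
is analyzed without constructing a hypnogram, which removes the
inter-scorer variability of manual staging.

## Method

1. **Continuous wavelet transform.** Each channel `EEG(t)` is transformed
   with the Morlet wavelet at ω₀ = 2π,

       W(s, t₀) = s^(-1/2) ∫ EEG(t) ψ*((t − t₀)/s) dt,
       ψ(t) = π^(-1/4) e^(iω₀t) e^(-t²/2),

   on a logarithmic scale grid covering 1–40 Hz. With ω₀ = 2π the scale
   corresponds to frequency, s ≈ 1/f.
2. **Skeleton.** At every time step the k = 7 largest across-scale local
   maxima of |W(s, t₀)| are kept — the ridge points carrying the
   oscillatory content.
3. **Pattern linking.** Ridge points at consecutive time steps whose
   scales differ by at most δs = 0.0008 s are chained into one
   oscillatory pattern. Each pattern gets a fundamental frequency
   Fm = mean(1/sᵢ) and duration T = t_end − t_start; patterns shorter
   than one fundamental period (T < 1/Fm) are discarded as noise.
4. **Band statistics.** Retained patterns are counted in twenty bands
   Δf₁ [1;2], Δf₂ [2;4], …, Δf₂₀ [38;40] Hz; counts are normalized to
   patterns per 30-s epoch (N), durations summarized per subject (T).
5. **Group comparison.** Subject-level N and T are compared per
   channel × band with the two-sided Mann–Whitney U test (exact null
   distribution up to combined n = 30 without ties); cells with
   p ≤ 0.001 are flagged, and percent differences are reported relative
   to the reference group.

Because clinical recordings cannot be redistributed, the package ships a
seeded synthetic-cohort generator (slow-wave-dominated background plus
per-band oscillatory bursts with controlled rates and durations) so
every stage of the pipeline is testable against known ground truth.

## Worked example

```python
import oscipat as op

# a small synthetic cohort: 3 subjects per group, 5-minute records
spec = op.CohortSpec(n_per_group=3, record_length=300.0,
                     channels=("O1",), seed=7)

# one record end to end
rec, burst_log = op.generate_record(spec, "A", 0, "O1")
patterns = op.analyze_record(rec, op.AnalysisConfig())
print(len(patterns))                      # 2441 retained patterns
table = op.summarize_subject(patterns, "A01", "O1", rec.duration)
print(table[table.band.isin([2, 19, 20])][["band", "N", "T_mean"]])
#  band     N   T_mean
#     2   9.1    0.498
#    19  31.6    0.073
#    20  19.5    0.114

# the full two-group study
_, _, comparison = op.run_cohort_study(spec)
n = comparison.table.query("metric == 'N' and band in (2, 19, 20)")
print(n[["band", "mean_a", "mean_b", "percent_difference", "p_value"]])
#  band  mean_a  mean_b  percent_difference  p_value
#     2   10.00    8.87                11.3     0.40
#    19   31.80   14.70                53.8     0.10
#    20   18.73    4.67                75.1     0.10
```

The generator imposed burst-rate reductions of 20% (Δf₂–Δf₄), 60%
(Δf₁₉) and 75% (Δf₂₀) on group B; the measured percent differences
recover the strong gamma-band contrasts almost exactly, and at n = 3
per group no cell can reach significance (the exact Mann–Whitney p
floor at 3 vs 3 is 0.1) — group sizes of ~14 are needed for the
p ≤ 0.001 criterion, as in a realistically sized study.

A command-line interface mirrors the library:

```sh
oscipat simulate --n-per-group 4 --record-seconds 600 --seed 1 --out cohort/
oscipat extract  --input cohort/group_A/A01.csv --channels O1,O2,C3,C4 --out outA/
oscipat compare  --group-a outA/ --group-b outB/ --alpha 0.001 --out report.csv
```

EDF/EDF+ files are read natively (`op.read_eeg("night.edf",
["O1", "O2", "C3", "C4"])`); delimited text is the fallback format for
simulation output and tests.

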