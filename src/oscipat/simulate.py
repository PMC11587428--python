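"""Synthetic polysomnographic-EEG cohorts for pipeline validation.

Real overnight recordings are not distributable, so validation runs on a
surrogate with the statistical structure the pipeline assumes: 1/f-like
Gaussian background plus transient oscillatory bursts (tapered sinusoids)
whose per-band rates and durations are controlled exactly.  Two simulated
groups differ by configurable per-band rate reductions; the defaults
emulate the contrast the method is designed to detect (a ~20% reduction
in the 2-8 Hz bands and 60% / 75% reductions in the 36-38 / 38-40 Hz
bands of the patient-like group).

Every record is a pure function of (seed, group, subject, channel), so a
cohort is reproducible byte-exactly without storing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfftfreq
from scipy.signal.windows import tukey

from .bands import assign_band, default_band_edges
from .config import DEFAULT_CHANNELS
from .records import SignalRecord

__all__ = [
    "BurstSpec",
    "CohortSpec",
    "default_burst_specs",
    "default_rate_effects",
    "Cohort",
    "generate_background",
    "generate_record",
    "generate_cohort",
    "sample_band_summaries",
]

GROUPS = ("A", "B")


@dataclass(frozen=True)
class BurstSpec:
    """One class of oscillatory bursts.

    Parameters
    ----------
    center_frequency
        Burst carrier frequency, Hz.
    rate
        Poisson mean number of bursts per 30 s (before group effects and
        the between-subject multiplier).
    duration_median, duration_sigma
        Lognormal duration distribution (median seconds, log-sd),
        truncated below at two carrier periods.
    amplitude
        Peak amplitude as a ratio to the background RMS.
    taper
        Tukey (raised-cosine) taper fraction of the burst envelope.
    """

    center_frequency: float
    rate: float = 12.0
    duration_median: float = 0.65
    duration_sigma: float = 0.25
    amplitude: float = 4.0
    taper: float = 0.5

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.duration_median < 2.0 / self.center_frequency:
            raise ValueError(
                "duration_median below two carrier periods"
            )

    @property
    def min_duration(self) -> float:
        return 2.0 / self.center_frequency


def default_burst_specs() -> List[BurstSpec]:
    """Burst classes of the default cohort: one per analysis band, so
    every band carries its own oscillatory events (as real EEG does) and
    group effects in one band are diluted rather than mirrored in its
    neighbours.

    Slow bursts are long (several carrier cycles) to keep their spectral
    skirt inside their own 2-Hz band; carriers next to the
    group-contrasted bands (2-8 Hz and 36-40 Hz) sit toward the far edge
    of their band to maximise scale separation from the contrast.  The
    contrasted bands run at a higher event rate, which sharpens the
    per-subject rate estimate the group comparison rests on."""
    specs = []
    for band, (f, rate, dur) in _DEFAULT_CLASSES.items():
        specs.append(
            BurstSpec(center_frequency=f, rate=rate, duration_median=dur,
                      taper=1.0)
        )
    return specs


def _band_carrier(band: int) -> float:
    """Carrier whose wavelet ridge falls at the band's geometric centre.

    The modulus ridge of a sinusoid at frequency f sits near f / 1.0124
    under the sqrt-normalized Morlet at omega0 = 2*pi, so the carrier is
    placed 1.24% above the geometric band centre; the ridge then has the
    largest possible margin to both band edges."""
    lo = 1.0 if band == 1 else 2.0 * (band - 1)
    hi = 2.0 * band
    return 1.0124 * float(np.sqrt(lo * hi))


#: band -> (carrier Hz or None for the computed centre,
#:           bursts per 30 s, median duration s).
#: The 2-8 Hz carriers are spread apart so that the time-frequency blob
#: of two co-active bursts from neighbouring classes has its centroid
#: inside a band, not on a band edge (geometric means 3.6, 5.8, 8.5 Hz).
_DEFAULT_RATES_DURS = {
    1: (None, 18.0, 1.4),
    2: (2.86, 12.0, 1.0),
    3: (4.60, 12.0, 0.8),
    4: (7.35, 12.0, 0.7),
    5: (9.90, 18.0, 0.4),
    **{b: (None, 6.0, 0.3) for b in range(6, 17)},
    17: (None, 18.0, 0.35),
    18: (None, 18.0, 0.35),
    19: (None, 12.0, 0.4),
    20: (None, 12.0, 0.4),
}

_DEFAULT_CLASSES = {
    b: (c if c is not None else _band_carrier(b), r, d)
    for b, (c, r, d) in _DEFAULT_RATES_DURS.items()
}


def default_rate_effects() -> Dict[int, float]:
    """Default group-B burst-rate reductions keyed by band index:
    20% in Df2-Df4 (2-8 Hz), 60% in Df19 (36-38 Hz), 75% in Df20
    (38-40 Hz)."""
    return {2: 0.20, 3: 0.20, 4: 0.20, 19: 0.60, 20: 0.75}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-group synthetic cohort.

    ``rate_effects`` / ``duration_effects`` map band index -> fractional
    reduction applied to group B (band of a burst class = band containing
    its carrier frequency).  Per-subject, per-band burst rates carry a
    gamma multiplier with CV ``subject_cv`` (shared across channels) and
    an independent per-channel gamma factor with CV ``channel_cv``
    (regional variation within a subject).
    """

    n_per_group: int = 14
    record_length: float = 1800.0
    sampling_rate: float = 200.0
    channels: Tuple[str, ...] = DEFAULT_CHANNELS
    background_exponent: float = 1.0
    background_cutoff_hz: Optional[float] = 0.5
    background_rms: float = 1.0
    bursts: Tuple[BurstSpec, ...] = field(
        default_factory=lambda: tuple(default_burst_specs())
    )
    rate_effects: Dict[int, float] = field(
        default_factory=default_rate_effects
    )
    duration_effects: Dict[int, float] = field(default_factory=dict)
    subject_cv: float = 0.02
    channel_cv: float = 0.03
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.record_length < 10 * self.epoch_seconds:
            raise ValueError("record_length must cover >= 10 epochs")
        nyq = self.sampling_rate / 2.0
        for b in self.bursts:
            if b.center_frequency >= nyq:
                raise ValueError(
                    f"burst frequency {b.center_frequency} Hz at or above "
                    f"Nyquist {nyq} Hz"
                )

    def burst_band(self, burst: BurstSpec) -> int:
        band = assign_band(burst.center_frequency)
        if band is None:
            raise ValueError(
                f"burst at {burst.center_frequency} Hz outside banded range"
            )
        return band

    def group_bursts(self, group: str) -> List[Tuple[BurstSpec, float, float]]:
        """Per burst class: (spec, effective rate, effective duration
        median) for a group."""
        out = []
        for b in self.bursts:
            band = self.burst_band(b)
            rate = b.rate
            dmed = b.duration_median
            if group == "B":
                rate *= 1.0 - self.rate_effects.get(band, 0.0)
                dmed *= 1.0 - self.duration_effects.get(band, 0.0)
            out.append((b, rate, dmed))
        return out


# ---------------------------------------------------------------------------
# Record synthesis
# ---------------------------------------------------------------------------

def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed) & 0x7FFFFFFF, *key])


def generate_background(
    n_samples: int,
    sampling_rate: float,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
    cutoff_hz: Optional[float] = None,
) -> np.ndarray:
    """Gaussian noise with power spectrum 1/f^exponent, scaled to a target
    RMS (the standard EEG background surrogate).

    With ``cutoff_hz`` the stochastic spectral content is confined below
    that frequency (emulating activity dominated by slow waves): above the
    cutoff only the smooth wavelet-domain tails of the slow components
    remain, so the background contributes essentially no ridge skeleton
    inside the analysis band and detected pattern rates stay aligned with
    the injected burst ground truth.  ``cutoff_hz=None`` gives the
    full-band power law (a broadband floor that adds band-dependent
    baseline pattern counts, useful for stress tests).
    """
    freqs = rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    if cutoff_hz is not None:
        amp[freqs > cutoff_hz] = 0.0
    coef = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    x = irfft(coef, n=n_samples)
    x *= rms / np.sqrt(np.mean(x ** 2))
    return x


def _gamma_unit_mean(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    return float(rng.gamma(shape=1.0 / cv ** 2, scale=cv ** 2))


def _subject_multiplier(
    spec: CohortSpec, group: str, subject: int, band: int
) -> float:
    """Gamma(mean 1, CV = subject_cv) rate multiplier, shared across the
    channels of a subject."""
    rng = _rng(spec.seed, GROUPS.index(group), subject, 2000 + band)
    return _gamma_unit_mean(rng, spec.subject_cv)


def _channel_multiplier(
    spec: CohortSpec, group: str, subject: int, band: int, channel_idx: int
) -> float:
    """Per-channel rate factor (gamma, mean 1, CV = channel_cv) on top of
    the subject-level multiplier: regional rhythm rates vary within a
    subject, so channels carry partly independent evidence."""
    rng = _rng(spec.seed, GROUPS.index(group), subject,
               3000 + band, channel_idx)
    return _gamma_unit_mean(rng, spec.channel_cv)


def generate_record(
    spec: CohortSpec, group: str, subject: int, channel: str
) -> Tuple[SignalRecord, pd.DataFrame]:
    """Synthesize one channel record and its ground-truth burst log.

    Deterministic given (spec.seed, group, subject, channel).  The log has
    one row per injected burst: ``t_start``, ``duration``, ``frequency``,
    ``band``, ``amplitude``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    if channel not in spec.channels:
        raise ValueError(f"unknown channel {channel!r}")
    ci = spec.channels.index(channel)
    rng = _rng(spec.seed, GROUPS.index(group), subject, ci)
    fs = spec.sampling_rate
    n = int(round(spec.record_length * fs))
    x = generate_background(n, fs, spec.background_exponent,
                            spec.background_rms, rng,
                            cutoff_hz=spec.background_cutoff_hz)

    log_rows = []
    t_axis = np.arange(n) / fs
    for burst, rate, dmed in spec.group_bursts(group):
        band = spec.burst_band(burst)
        mult = (_subject_multiplier(spec, group, subject, band)
                * _channel_multiplier(spec, group, subject, band, ci))
        mean_count = rate * mult * spec.record_length / spec.epoch_seconds
        count = rng.poisson(mean_count)
        for _ in range(count):
            dur = _sample_duration(rng, dmed, burst.duration_sigma,
                                   burst.min_duration)
            dur = min(dur, spec.record_length * 0.5)
            t0 = rng.uniform(0.0, spec.record_length - dur)
            i0 = int(round(t0 * fs))
            ln = max(int(round(dur * fs)), 2)
            if i0 + ln > n:
                ln = n - i0
            phase = rng.uniform(0.0, 2.0 * np.pi)
            seg = t_axis[i0: i0 + ln]
            wave = np.sin(2.0 * np.pi * burst.center_frequency * seg + phase)
            wave *= tukey(ln, alpha=burst.taper)
            x[i0: i0 + ln] += burst.amplitude * spec.background_rms * wave
            log_rows.append(
                {"t_start": t0, "duration": ln / fs,
                 "frequency": burst.center_frequency, "band": band,
                 "amplitude": burst.amplitude}
            )
    log = pd.DataFrame(
        log_rows,
        columns=["t_start", "duration", "frequency", "band", "amplitude"],
    ).sort_values("t_start", ignore_index=True)
    rec = SignalRecord(channel_label=channel, sampling_rate=fs, samples=x)
    return rec, log


def _sample_duration(
    rng: np.random.Generator, median: float, sigma: float, minimum: float
) -> float:
    for _ in range(200):
        d = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        if d >= minimum:
            return d
    return minimum


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

class Cohort:
    """Lazy two-group cohort: records are regenerated on demand from the
    spec (deterministic), so a full cohort never needs to sit in memory."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec

    def subjects(self, group: str) -> List[str]:
        return [f"{group}{i + 1:02d}" for i in range(self.spec.n_per_group)]

    def record(self, group: str, subject: int, channel: str):
        return generate_record(self.spec, group, subject, channel)

    def iter_records(
        self, group: str
    ) -> Iterator[Tuple[str, str, SignalRecord, pd.DataFrame]]:
        """Yield (subject_id, channel, record, burst_log) for a group."""
        for i in range(self.spec.n_per_group):
            sid = f"{group}{i + 1:02d}"
            for ch in self.spec.channels:
                rec, log = self.record(group, i, ch)
                yield sid, ch, rec, log

    def manifest(self) -> dict:
        """Ground truth: per-group per-band expected burst rates (per
        30 s, averaged over subjects' multipliers) and per-subject true
        rates."""
        out = {"seed": self.spec.seed, "groups": {}}
        for g in GROUPS:
            rates_by_band: Dict[int, float] = {}
            for burst, rate, _ in self.spec.group_bursts(g):
                band = self.spec.burst_band(burst)
                rates_by_band[band] = rates_by_band.get(band, 0.0) + rate
            subjects = {}
            for i in range(self.spec.n_per_group):
                per_band = {}
                for band, rate in rates_by_band.items():
                    per_band[band] = rate * _subject_multiplier(
                        self.spec, g, i, band
                    )
                subjects[f"{g}{i + 1:02d}"] = per_band
            out["groups"][g] = {
                "nominal_rates_per_band": rates_by_band,
                "subject_rates_per_band": subjects,
            }
        return out


def generate_cohort(
    spec: CohortSpec,
    out_dir: Optional[str] = None,
    overwrite: bool = False,
) -> Cohort:
    """Build a cohort; optionally write it to disk.

    With ``out_dir``, writes one delimited file per subject x group
    (columns ``time`` then one per channel), per-record burst logs, and a
    JSON ground-truth manifest.  Raises if the directory already holds a
    manifest, unless ``overwrite``.
    """
    cohort = Cohort(spec)
    if out_dir is None:
        return cohort
    root = Path(out_dir)
    manifest_path = root / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (pass overwrite=True)")
    root.mkdir(parents=True, exist_ok=True)
    for g in GROUPS:
        gdir = root / f"group_{g}"
        gdir.mkdir(exist_ok=True)
        for i in range(spec.n_per_group):
            sid = f"{g}{i + 1:02d}"
            cols = {}
            logs = []
            for ch in spec.channels:
                rec, log = cohort.record(g, i, ch)
                cols[ch] = rec.samples
                log = log.assign(channel=ch)
                logs.append(log)
            n = len(next(iter(cols.values())))
            df = pd.DataFrame(
                {"time": np.arange(n) / spec.sampling_rate, **cols}
            )
            df.to_csv(gdir / f"{sid}.csv", index=False)
            pd.concat(logs, ignore_index=True).to_csv(
                gdir / f"{sid}_bursts.csv", index=False
            )
    with open(manifest_path, "w") as fh:
        spec_dict = asdict(spec)
        spec_dict["bursts"] = [asdict(b) for b in spec.bursts]
        json.dump({"spec": spec_dict, "truth": cohort.manifest()}, fh,
                  indent=2, default=str)
    return cohort


# ---------------------------------------------------------------------------
# Distributional layer (no waveforms)
# ---------------------------------------------------------------------------

def sample_band_summaries(
    n_subjects: int,
    rates: Dict[int, float],
    n_epochs: int,
    subject_cv: float,
    seed: int,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    duration_medians: Optional[Dict[int, float]] = None,
    duration_sigma: float = 0.25,
    group_label: str = "A",
    n_bands: int = 20,
) -> pd.DataFrame:
    """Draw subject-level band summaries directly from the cohort's rate
    model, skipping waveform synthesis.

    Per subject x channel x band: the pattern count over ``n_epochs``
    epochs is Poisson with mean ``rate * gamma_multiplier * n_epochs``
    (multiplier shared across channels), N is the per-epoch mean, and the
    duration mean is that of lognormal burst durations.  This is the
    generative model the full pipeline estimates; it is used where many
    cohort replicates are needed (e.g. null calibration of the group
    comparison).

    Bands absent from ``rates`` get rate 0 (N = 0, duration missing).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 4000])
    if duration_medians is None:
        duration_medians = {}
    rows = []
    cv2 = subject_cv ** 2 if subject_cv > 0 else 0.0
    for i in range(n_subjects):
        sid = f"{group_label}{i + 1:02d}"
        mults = {
            band: (rng.gamma(1.0 / cv2, cv2) if cv2 > 0 else 1.0)
            for band in range(1, n_bands + 1)
        }
        for ch in channels:
            for band in range(1, n_bands + 1):
                rate = rates.get(band, 0.0)
                lam = rate * mults[band] * n_epochs
                count = rng.poisson(lam) if lam > 0 else 0
                dmed = duration_medians.get(band, 0.65)
                if count > 0:
                    durs = np.exp(
                        np.log(dmed)
                        + duration_sigma * rng.standard_normal(count)
                    )
                    t_mean = float(np.mean(durs))
                    t_median = float(np.median(durs))
                    t_sd = float(np.std(durs, ddof=1)) if count > 1 else np.nan
                else:
                    t_mean = t_median = t_sd = np.nan
                rows.append(
                    {"subject": sid, "channel": ch, "band": band,
                     "N": count / n_epochs, "T_mean": t_mean,
                     "T_median": t_median, "T_sd": t_sd,
                     "n_patterns_total": count}
                )
    return pd.DataFrame(rows)
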