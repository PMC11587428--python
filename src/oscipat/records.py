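"""The in-memory EEG container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SignalRecord:
    """One channel of uniformly sampled EEG.

    Attributes
    ----------
    channel_label
        Electrode name (e.g. ``"O1"``).
    sampling_rate
        Samples per second (Hz), > 0.
    samples
        Amplitude sequence, arbitrary units (typically microvolts).
    start_time
        Optional recording start (seconds since an arbitrary origin or a
        timestamp); informational only.
    """

    channel_label: str
    sampling_rate: float
    samples: np.ndarray
    start_time: Optional[float] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def validate_for_analysis(self, freq_min: float, freq_max: float) -> None:
        """Check the record supports analysis over [freq_min, freq_max] Hz.

        Requires at least two periods of the slowest analyzed oscillation
        and a sampling rate satisfying Nyquist for the fastest one.
        """
        if self.sampling_rate < 2.0 * freq_max:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz below Nyquist "
                f"requirement {2.0 * freq_max} Hz for freq_max={freq_max} Hz"
            )
        min_len = 2.0 * self.sampling_rate / freq_min
        if self.n_samples < min_len:
            raise ValueError(
                f"record too short: {self.n_samples} samples < "
                f"{min_len:.0f} (two periods at {freq_min} Hz)"
            )
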