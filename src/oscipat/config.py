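"""Analysis configuration.

All tunable parameters of the pattern pipeline live in a single
:class:`AnalysisConfig` so that a run is fully described by one object
(echoed into run metadata for reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

#: EEG channels analyzed by default (occipital and central, 10-20 montage).
DEFAULT_CHANNELS = ("O1", "O2", "C3", "C4")

#: Montage label aliases.  PSG systems label channels in many ways
#: ("EEG O1-M2", "O1-A2", ...); keys are canonical labels, values are
#: normalization applied before matching (see io.read_eeg).
REFERENCE_SUFFIXES = ("-M1", "-M2", "-A1", "-A2", "-M", "-A", "-REF", "-LE")
CHANNEL_PREFIXES = ("EEG ", "EEG-", "EEG_")


def normalize_channel_label(label: str) -> str:
    """Reduce a montage label to its canonical electrode name.

    ``"EEG O1-M2"`` -> ``"O1"``; matching is case-insensitive.
    """
    out = label.strip().upper()
    for pre in CHANNEL_PREFIXES:
        if out.startswith(pre):
            out = out[len(pre):]
            break
    for suf in REFERENCE_SUFFIXES:
        if out.endswith(suf):
            out = out[: -len(suf)]
            break
    return out.strip()


@dataclass
class AnalysisConfig:
    """Parameters of the oscillatory-pattern pipeline.

    Parameters
    ----------
    channels
        EEG channel labels to analyze.
    freq_min, freq_max
        Analysis frequency range in Hz.  The scale grid covers
        ``[freq_min, freq_max]`` (with one guard scale beyond each end so
        that ridges at the range edges remain interior local maxima).
    n_scales
        Number of scale-grid points covering ``[freq_min, freq_max]``,
        logarithmically spaced.  The default (117, ~22 voices per octave
        over 1-40 Hz) is the finest log grid whose adjacent-scale gap
        still exceeds the default linking threshold ``delta_s``
        everywhere, and it gives every 2-Hz analysis band at least two
        grid frequencies, so a ridge jittering by one grid step stays
        inside its band.
    omega0
        Morlet central frequency in radians; 2*pi makes scale ~ 1/frequency.
    cwt_norm
        ``"sqrt"`` for the L2 (1/sqrt(s)) wavelet normalization (default),
        ``"linear"`` for 1/s.
    skeleton_k
        Number of largest across-scale modulus maxima retained per time
        step (the skeleton width).
    skeleton_mode
        ``"local_maxima"`` (default): the k largest *local* maxima of the
        modulus across scale.  ``"topk"``: the k largest values regardless
        of local-maximum structure.
    delta_s
        Scale-proximity threshold (seconds) for chaining skeleton points
        at consecutive time steps into one pattern.
    epoch_seconds
        Normalization window for pattern counts (patterns per epoch).
    alpha
        Significance level of the group comparison.
    band_pass
        Optional ``(low, high)`` Hz pre-filter; ``None`` disables
        pre-filtering (the default: raw referenced EEG is analyzed as-is).
    notch_hz
        Optional mains-notch frequency; ``None`` disables.
    block_seconds
        Records longer than this are transformed in overlapping blocks
        (identical result, bounded memory).
    seed
        Seed for any stochastic step.
    """

    channels: tuple = DEFAULT_CHANNELS
    freq_min: float = 1.0
    freq_max: float = 40.0
    n_scales: int = 117
    omega0: float = 2.0 * np.pi
    cwt_norm: str = "sqrt"
    skeleton_k: int = 7
    skeleton_mode: str = "local_maxima"
    delta_s: float = 0.0008
    epoch_seconds: float = 30.0
    alpha: float = 0.001
    band_pass: Optional[tuple] = None
    notch_hz: Optional[float] = None
    block_seconds: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.freq_min < self.freq_max):
            raise ValueError("require 0 < freq_min < freq_max")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.skeleton_k < 1:
            raise ValueError("skeleton_k must be >= 1")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be > 0")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.cwt_norm not in ("sqrt", "linear"):
            raise ValueError("cwt_norm must be 'sqrt' or 'linear'")
        if self.skeleton_mode not in ("local_maxima", "topk"):
            raise ValueError("skeleton_mode must be 'local_maxima' or 'topk'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d
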