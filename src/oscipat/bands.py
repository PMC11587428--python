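"""The twenty analysis frequency bands and per-subject band summaries.

Bands are Df1 [1;2], Df2 [2;4], Df3 [4;6], ..., Df20 [38;40] Hz --
contiguous, 2 Hz wide except the first.  Shared endpoints are resolved
with the half-open convention [low, high), closed at the top edge
(Fm = 40 Hz belongs to Df20), the only overlap-free reading of the
printed boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .patterns import PatternSet

__all__ = [
    "BandDefinition",
    "default_bands",
    "default_band_edges",
    "assign_band",
    "assign_band_indices",
    "summarize_subject",
]


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band: half-open [f_low, f_high) Hz (the last band is
    closed at the top)."""

    index: int
    f_low: float
    f_high: float

    @property
    def label(self) -> str:
        return f"Df{self.index}"


def default_band_edges() -> np.ndarray:
    """Edges of the default 20 bands: [1, 2, 4, 6, ..., 40] Hz."""
    return np.concatenate(([1.0], np.arange(2.0, 41.0, 2.0)))


def default_bands() -> List[BandDefinition]:
    edges = default_band_edges()
    return [
        BandDefinition(index=i + 1, f_low=float(edges[i]),
                       f_high=float(edges[i + 1]))
        for i in range(len(edges) - 1)
    ]


def _validate_edges(band_edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("band_edges must be a 1-D array of >= 2 edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing "
                         "(overlapping band definitions)")
    return edges


def assign_band_indices(fm: np.ndarray, band_edges: np.ndarray) -> np.ndarray:
    """Vectorized band assignment.

    Returns 0-based band indices; -1 for frequencies outside
    [edges[0], edges[-1]].  Half-open [low, high) bands, closed top edge.
    """
    edges = _validate_edges(band_edges)
    fm = np.asarray(fm, dtype=float)
    idx = np.searchsorted(edges, fm, side="right") - 1
    idx[fm == edges[-1]] = len(edges) - 2  # closed top edge
    out_of_range = (fm < edges[0]) | (fm > edges[-1])
    idx[out_of_range] = -1
    return idx.astype(np.int64)


def assign_band(
    fm: float, bands: Optional[List[BandDefinition]] = None
) -> Optional[int]:
    """Band index (1-based) for a fundamental frequency, or None if the
    frequency falls outside the banded range."""
    if bands is None:
        bands = default_bands()
    edges = np.array([b.f_low for b in bands] + [bands[-1].f_high])
    _validate_edges(edges)
    idx = assign_band_indices(np.array([fm]), edges)[0]
    return None if idx < 0 else int(idx) + 1


def summarize_subject(
    patterns: PatternSet,
    subject_id: str,
    channel: str,
    record_length: float,
    band_edges: Optional[np.ndarray] = None,
    epoch_seconds: float = 30.0,
) -> pd.DataFrame:
    """Per-band summary for one subject and channel.

    ``N`` is the mean pattern count per complete epoch;
    duration statistics (seconds) are over that band's retained patterns.
    Patterns with Fm outside the banded range are excluded from every band
    and reported in the returned frame's ``attrs["overflow"]`` bucket.

    Returns one row per band with columns ``subject``, ``channel``,
    ``band``, ``N``, ``T_mean``, ``T_median``, ``T_sd``,
    ``n_patterns_total``.
    """
    if band_edges is None:
        band_edges = default_band_edges()
    edges = _validate_edges(band_edges)
    n_bands = len(edges) - 1
    n_epochs = int(np.floor(record_length / epoch_seconds))
    if n_epochs < 1:
        raise ValueError("record shorter than one epoch")

    band = assign_band_indices(patterns.fm, edges)
    epoch = np.floor(patterns.t_start / epoch_seconds).astype(np.int64)
    inside = epoch < n_epochs  # final partial epoch dropped
    dur = patterns.duration

    rows = []
    for b in range(n_bands):
        sel = (band == b) & inside
        n_tot = int(sel.sum())
        d = dur[sel]
        rows.append(
            {
                "subject": subject_id,
                "channel": channel,
                "band": b + 1,
                "N": n_tot / n_epochs,
                "T_mean": float(np.mean(d)) if n_tot else np.nan,
                "T_median": float(np.median(d)) if n_tot else np.nan,
                "T_sd": float(np.std(d, ddof=1)) if n_tot > 1 else np.nan,
                "n_patterns_total": n_tot,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overflow"] = int(((band < 0) & inside).sum())
    out.attrs["n_epochs"] = n_epochs
    return out
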