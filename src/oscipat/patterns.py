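"""Chaining skeleton points into oscillatory patterns.

Ridge points at consecutive time steps whose scales differ by at most
``delta_s`` (default 0.0008 s) belong to one *oscillatory pattern* -- a
transient rhythmic event.  Each pattern is characterized by its duration
T = t_end - t_start and fundamental frequency Fm = mean(1/s_i) over its
points; patterns shorter than one fundamental period (T < 1/Fm) are
treated as noise and excluded.  Counts are then normalized to 30-second
epochs.

Linking rule (deterministic): at each time step, pattern heads are
processed in descending modulus of the head point (ties toward the lower
scale); each head claims the unclaimed next-frame point nearest in scale
within ``delta_s`` (ties toward the lower scale); no point is shared
between patterns; unmatched next-frame points start new patterns.

When ``delta_s`` is smaller than the smallest gap between adjacent grid
scales -- true for the default grid -- a link can only join points at the
*same* grid scale, and linking reduces to finding maximal same-scale runs
of consecutive time steps.  That equivalent fast path is used
automatically; the general greedy matcher handles arbitrary inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cwt import Skeleton, SkeletonFrame

__all__ = [
    "Pattern",
    "PatternSet",
    "link_patterns",
    "fundamental_frequency",
    "noise_filter",
    "normalize_to_epochs",
]


@dataclass
class Pattern:
    """One oscillatory pattern: ridge points at consecutive time steps.

    ``points`` are (time_seconds, scale_seconds, modulus) triples.
    """

    points: List[Tuple[float, float, float]]
    time_step: float
    channel_label: str = ""

    @property
    def t_start(self) -> float:
        return self.points[0][0]

    @property
    def t_end(self) -> float:
        return self.points[-1][0]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def fundamental_frequency(self) -> float:
        return fundamental_frequency(self)

    @property
    def n_points(self) -> int:
        return len(self.points)


def fundamental_frequency(pattern: Pattern) -> float:
    """Mean instantaneous frequency of a pattern: mean of 1/s_i (Hz)."""
    if not pattern.points:
        raise ValueError("empty pattern")
    scales = np.array([p[1] for p in pattern.points])
    if np.any(scales <= 0):
        raise ValueError("non-positive scale in pattern")
    return float(np.mean(1.0 / scales))


class PatternSet:
    """Container of patterns from one record/channel, stored as arrays.

    Per-pattern arrays: ``start_idx``/``end_idx`` (time-step indices),
    ``fm`` (Hz).  Per-point arrays (ordered by pattern, then time):
    ``pt_pattern``, ``pt_time_idx``, ``pt_scale``, ``pt_modulus``.
    Iterating yields :class:`Pattern` objects.
    """

    def __init__(
        self,
        start_idx: np.ndarray,
        end_idx: np.ndarray,
        fm: np.ndarray,
        pt_pattern: np.ndarray,
        pt_time_idx: np.ndarray,
        pt_scale: np.ndarray,
        pt_modulus: np.ndarray,
        time_step: float,
        time_offset: float = 0.0,
        channel_label: str = "",
    ):
        self.start_idx = np.asarray(start_idx, dtype=np.int64)
        self.end_idx = np.asarray(end_idx, dtype=np.int64)
        self.fm = np.asarray(fm, dtype=float)
        self.pt_pattern = np.asarray(pt_pattern, dtype=np.int64)
        self.pt_time_idx = np.asarray(pt_time_idx, dtype=np.int64)
        self.pt_scale = np.asarray(pt_scale, dtype=float)
        self.pt_modulus = np.asarray(pt_modulus, dtype=float)
        self.time_step = time_step
        self.time_offset = time_offset
        self.channel_label = channel_label

    # -- derived quantities -------------------------------------------------

    def __len__(self) -> int:
        return self.start_idx.size

    @property
    def t_start(self) -> np.ndarray:
        return self.time_offset + self.start_idx * self.time_step

    @property
    def t_end(self) -> np.ndarray:
        return self.time_offset + self.end_idx * self.time_step

    @property
    def duration(self) -> np.ndarray:
        return (self.end_idx - self.start_idx) * self.time_step

    @property
    def n_points(self) -> np.ndarray:
        return self.end_idx - self.start_idx + 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format pattern table (one row per pattern)."""
        return pd.DataFrame(
            {
                "channel": self.channel_label,
                "t_start": self.t_start,
                "t_end": self.t_end,
                "duration": self.duration,
                "fm": self.fm,
                "n_points": self.n_points,
            }
        )

    def __iter__(self) -> Iterator[Pattern]:
        order = np.argsort(self.pt_pattern, kind="stable")
        bounds = np.searchsorted(self.pt_pattern[order], np.arange(len(self) + 1))
        for p in range(len(self)):
            sl = order[bounds[p]: bounds[p + 1]]
            sl = sl[np.argsort(self.pt_time_idx[sl], kind="stable")]
            pts = [
                (
                    self.time_offset + float(self.pt_time_idx[i]) * self.time_step,
                    float(self.pt_scale[i]),
                    float(self.pt_modulus[i]),
                )
                for i in sl
            ]
            yield Pattern(points=pts, time_step=self.time_step,
                          channel_label=self.channel_label)

    def select(self, keep: np.ndarray) -> "PatternSet":
        """Subset by a boolean mask over patterns (order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        new_id = -np.ones(len(self), dtype=np.int64)
        new_id[keep] = np.arange(int(keep.sum()))
        pt_keep = keep[self.pt_pattern]
        return PatternSet(
            start_idx=self.start_idx[keep],
            end_idx=self.end_idx[keep],
            fm=self.fm[keep],
            pt_pattern=new_id[self.pt_pattern[pt_keep]],
            pt_time_idx=self.pt_time_idx[pt_keep],
            pt_scale=self.pt_scale[pt_keep],
            pt_modulus=self.pt_modulus[pt_keep],
            time_step=self.time_step,
            time_offset=self.time_offset,
            channel_label=self.channel_label,
        )


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _link_general(
    frames: Sequence[List[Tuple[float, float]]], delta_s: float
) -> List[List[Tuple[int, float, float]]]:
    """Greedy nearest-scale chaining over explicit frames.

    ``frames[t]`` is a list of (scale, modulus) sorted by descending
    modulus.  Returns patterns as lists of (time_idx, scale, modulus).
    """
    patterns: List[List[Tuple[int, float, float]]] = []
    active: List[int] = []  # pattern indices whose head is in frame t-1
    for t, pts in enumerate(frames):
        # heads in descending head-point modulus, tie -> lower scale
        heads = sorted(
            active,
            key=lambda p: (-patterns[p][-1][2], patterns[p][-1][1]),
        )
        claimed = [False] * len(pts)
        new_active: List[int] = []
        for p in heads:
            hs = patterns[p][-1][1]
            best = -1
            best_d = None
            for j, (s, m) in enumerate(pts):
                if claimed[j]:
                    continue
                d = abs(s - hs)
                if d <= delta_s and (
                    best < 0 or d < best_d or (d == best_d and s < pts[best][0])
                ):
                    best, best_d = j, d
            if best >= 0:
                claimed[best] = True
                patterns[p].append((t, pts[best][0], pts[best][1]))
                new_active.append(p)
        for j, (s, m) in enumerate(pts):
            if not claimed[j]:
                new_active.append(len(patterns))
                patterns.append([(t, s, m)])
        active = new_active
    return patterns


def _patterns_from_lists(
    plists: List[List[Tuple[int, float, float]]],
    time_step: float,
    time_offset: float,
    channel_label: str,
) -> PatternSet:
    # deterministic order: by (start time index, scale of first point)
    plists = sorted(plists, key=lambda pl: (pl[0][0], pl[0][1]))
    n = len(plists)
    start = np.empty(n, dtype=np.int64)
    end = np.empty(n, dtype=np.int64)
    fm = np.empty(n, dtype=float)
    pt_p, pt_t, pt_s, pt_m = [], [], [], []
    for i, pl in enumerate(plists):
        start[i] = pl[0][0]
        end[i] = pl[-1][0]
        fm[i] = np.mean([1.0 / s for (_, s, _) in pl])
        for (t, s, m) in pl:
            pt_p.append(i)
            pt_t.append(t)
            pt_s.append(s)
            pt_m.append(m)
    return PatternSet(
        start_idx=start, end_idx=end, fm=fm,
        pt_pattern=np.array(pt_p, dtype=np.int64),
        pt_time_idx=np.array(pt_t, dtype=np.int64),
        pt_scale=np.array(pt_s, dtype=float),
        pt_modulus=np.array(pt_m, dtype=float),
        time_step=time_step, time_offset=time_offset,
        channel_label=channel_label,
    )


def _link_same_scale_runs(
    skeleton: Skeleton, channel_label: str
) -> PatternSet:
    """Fast path: patterns are maximal same-grid-scale runs of consecutive
    time steps.  Exactly equivalent to the greedy matcher whenever
    ``delta_s`` is below the smallest adjacent-scale gap of the grid."""
    n_s = skeleton.grid.n_scales
    n_t = skeleton.n_times
    scales = skeleton.grid.scales

    occ = np.zeros((n_s, n_t), dtype=bool)
    modg = np.zeros((n_s, n_t), dtype=float)
    valid = skeleton.scale_idx >= 0
    tcols = np.broadcast_to(np.arange(n_t), skeleton.scale_idx.shape)[valid]
    srows = skeleton.scale_idx[valid]
    occ[srows, tcols] = True
    modg[srows, tcols] = skeleton.modulus[valid]

    starts_all, ends_all, rows_all = [], [], []
    pt_t_all, pt_row_all, pt_m_all, pt_pat_all = [], [], [], []
    run_offset = 0
    for r in range(n_s):
        row = occ[r]
        if not row.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], row, [False]))))
        rs, re = edges[::2], edges[1::2] - 1
        starts_all.append(rs)
        ends_all.append(re)
        rows_all.append(np.full(rs.size, r, dtype=np.int64))
        ts = np.flatnonzero(row)
        pt_t_all.append(ts)
        pt_row_all.append(np.full(ts.size, r, dtype=np.int64))
        pt_m_all.append(modg[r, ts])
        pt_pat_all.append(np.searchsorted(rs, ts, side="right") - 1 + run_offset)
        run_offset += rs.size

    if run_offset == 0:
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return PatternSet(zi, zi, z, zi, zi, z, z,
                          time_step=skeleton.time_step,
                          time_offset=skeleton.time_offset,
                          channel_label=channel_label)

    start = np.concatenate(starts_all)
    end = np.concatenate(ends_all)
    rows = np.concatenate(rows_all)
    pt_pat = np.concatenate(pt_pat_all)
    pt_t = np.concatenate(pt_t_all)
    pt_row = np.concatenate(pt_row_all)
    pt_m = np.concatenate(pt_m_all)

    # deterministic pattern order: (start index, scale of first point)
    order = np.lexsort((scales[rows], start))
    rank = np.empty(order.size, dtype=np.int64)
    rank[order] = np.arange(order.size)
    return PatternSet(
        start_idx=start[order],
        end_idx=end[order],
        fm=1.0 / scales[rows][order],
        pt_pattern=rank[pt_pat],
        pt_time_idx=pt_t,
        pt_scale=scales[pt_row],
        pt_modulus=pt_m,
        time_step=skeleton.time_step,
        time_offset=skeleton.time_offset,
        channel_label=channel_label,
    )


def link_patterns(
    skeleton: Union[Skeleton, Iterable[SkeletonFrame]],
    delta_s: float = 0.0008,
    time_step: Optional[float] = None,
    channel_label: str = "",
    force_general: bool = False,
) -> PatternSet:
    """Chain skeleton points at consecutive time steps into patterns.

    Accepts a :class:`Skeleton` or an iterable of :class:`SkeletonFrame`
    (then ``time_step`` is required).  Single isolated points form
    single-point patterns (zero duration; removed later by the noise
    filter).
    """
    if delta_s <= 0:
        raise ValueError("delta_s must be > 0")
    if isinstance(skeleton, Skeleton):
        if not force_general and skeleton.grid.min_adjacent_gap() > delta_s:
            return _link_same_scale_runs(skeleton, channel_label)
        frames = [f.points for f in skeleton.frames()]
        return _patterns_from_lists(
            _link_general(frames, delta_s),
            time_step=skeleton.time_step,
            time_offset=skeleton.time_offset,
            channel_label=channel_label,
        )
    frames_list = list(skeleton)
    if time_step is None:
        raise ValueError("time_step required when passing raw frames")
    pts = [f.points for f in frames_list]
    return _patterns_from_lists(
        _link_general(pts, delta_s),
        time_step=time_step, time_offset=0.0, channel_label=channel_label,
    )


# ---------------------------------------------------------------------------
# Noise filter and epoch normalization
# ---------------------------------------------------------------------------

def noise_filter(patterns: PatternSet) -> PatternSet:
    """Drop patterns with duration strictly shorter than one fundamental
    period (T < 1/Fm); the boundary case T = 1/Fm is retained."""
    keep = patterns.duration >= 1.0 / patterns.fm
    return patterns.select(keep)


def normalize_to_epochs(
    patterns: PatternSet,
    record_length: float,
    epoch_seconds: float = 30.0,
    band_edges: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-epoch pattern counts and mean durations.

    Patterns are assigned to the epoch containing their start time
    (boundary ties go to the later epoch); a final partial epoch is
    dropped.  Returns a table with one row per complete epoch (and per
    band, if ``band_edges`` from :mod:`oscipat.bands` are given) with
    columns ``epoch_index``, (``band``,) ``count``, ``t_mean`` (NaN when
    the epoch holds no patterns).
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be > 0")
    n_epochs = int(np.floor(record_length / epoch_seconds))
    if n_epochs < 1:
        raise ValueError("record shorter than one epoch")
    t0 = patterns.t_start
    dur = patterns.duration
    epoch = np.floor(t0 / epoch_seconds).astype(np.int64)
    inside = epoch < n_epochs

    if band_edges is None:
        counts = np.bincount(epoch[inside], minlength=n_epochs)
        dsum = np.bincount(epoch[inside], weights=dur[inside],
                           minlength=n_epochs)
        with np.errstate(invalid="ignore"):
            t_mean = np.where(counts > 0, dsum / np.maximum(counts, 1), np.nan)
        return pd.DataFrame(
            {"epoch_index": np.arange(n_epochs), "count": counts,
             "t_mean": t_mean}
        )

    from .bands import assign_band_indices  # local import, no cycle at load

    band = assign_band_indices(patterns.fm, band_edges)
    n_bands = len(band_edges) - 1
    ok = inside & (band >= 0)
    flat = epoch[ok] * n_bands + band[ok]
    counts = np.bincount(flat, minlength=n_epochs * n_bands)
    dsum = np.bincount(flat, weights=dur[ok], minlength=n_epochs * n_bands)
    with np.errstate(invalid="ignore"):
        t_mean = np.where(counts > 0, dsum / np.maximum(counts, 1), np.nan)
    idx = np.arange(n_epochs * n_bands)
    return pd.DataFrame(
        {
            "epoch_index": idx // n_bands,
            "band": idx % n_bands + 1,
            "count": counts,
            "t_mean": t_mean,
        }
    )
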