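"""Pattern linking, fundamental frequency, noise filter, epoch counts."""

import numpy as np
import pytest

import oscipat as op
from oscipat.cwt import Skeleton, SkeletonFrame
from oscipat.patterns import link_patterns, noise_filter, normalize_to_epochs


def frames_from_points(points_per_frame):
    """Build SkeletonFrame list from [(scale, modulus), ...] per frame,
    sorting each frame by descending modulus as the extractor does."""
    out = []
    for t, pts in enumerate(points_per_frame):
        pts = sorted(pts, key=lambda p: (-p[1], p[0]))
        out.append(SkeletonFrame(time_index=t, points=list(pts)))
    return out


def oracle_link(frames, delta_s):
    """Independent re-statement of the linking rule: greedy nearest-scale
    matching, heads in descending head modulus (tie: lower scale), link
    tie broken toward the lower scale; no point shared."""
    patterns = []
    active = []
    for t, frame in enumerate(frames):
        pts = list(frame.points)
        taken = set()
        survivors = []
        for pi in sorted(active,
                         key=lambda p: (-patterns[p][-1][2],
                                        patterns[p][-1][1])):
            head_scale = patterns[pi][-1][1]
            cands = [
                (abs(s - head_scale), s, j)
                for j, (s, m) in enumerate(pts)
                if j not in taken and abs(s - head_scale) <= delta_s
            ]
            if cands:
                _, _, j = min(cands)
                taken.add(j)
                patterns[pi].append((t, pts[j][0], pts[j][1]))
                survivors.append(pi)
        for j, (s, m) in enumerate(pts):
            if j not in taken:
                survivors.append(len(patterns))
                patterns.append([(t, s, m)])
        active = survivors
    return sorted(patterns, key=lambda pl: (pl[0][0], pl[0][1]))


def as_point_lists(pattern_set):
    return sorted(
        [[(round(p[0] / pattern_set.time_step), p[1], p[2])
          for p in pat.points] for pat in pattern_set],
        key=lambda pl: (pl[0][0], pl[0][1]),
    )


class TestLinkPatterns:
    def test_two_frames_same_scale_one_pattern(self):
        frames = frames_from_points([[(0.1, 1.0)], [(0.1, 0.9)]])
        ps = link_patterns(frames, delta_s=0.0008, time_step=0.01)
        assert len(ps) == 1
        assert ps.n_points[0] == 2

    def test_scale_jump_beyond_delta_s_splits(self):
        frames = frames_from_points([[(0.100, 1.0)], [(0.102, 0.9)]])
        ps = link_patterns(frames, delta_s=0.0008, time_step=0.01)
        assert len(ps) == 2
        assert list(ps.n_points) == [1, 1]

    def test_matches_oracle_on_random_skeletons(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n_frames = int(rng.integers(2, 7))
            frames = frames_from_points([
                [(float(rng.choice([0.1, 0.1004, 0.101, 0.2])),
                  float(rng.random()))
                 for _ in range(rng.integers(0, 4))]
                for _ in range(n_frames)
            ])
            # drop duplicate scales within a frame (extractor guarantees)
            for f in frames:
                seen, uniq = set(), []
                for s, m in f.points:
                    if s not in seen:
                        seen.add(s)
                        uniq.append((s, m))
                f.points = uniq
            ps = link_patterns(frames, delta_s=0.0008, time_step=0.01)
            ref = oracle_link(frames, 0.0008)
            got = as_point_lists(ps)
            ref_cmp = [[(t, s, m) for (t, s, m) in pl] for pl in ref]
            assert got == ref_cmp

    def test_fast_and_general_paths_agree_on_real_record(self):
        rng = np.random.default_rng(2)
        fs = 200.0
        x = rng.standard_normal(int(20 * fs))
        rec = op.SignalRecord("O1", fs, x)
        cfg = op.AnalysisConfig(n_scales=60)
        grid = op.make_grid(cfg)
        spec = op.compute_cwt(rec, grid, keep_coefficients=False)
        sk = op.extract_skeleton(spec, k=7)
        fast = link_patterns(sk, delta_s=cfg.delta_s)
        slow = link_patterns(sk, delta_s=cfg.delta_s, force_general=True)
        assert as_point_lists(fast) == as_point_lists(slow)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(8)
        frames = frames_from_points([
            [(float(rng.choice([0.05, 0.0504, 0.3])), float(rng.random()))
             for _ in range(3)]
            for _ in range(5)
        ])
        a = link_patterns(frames, delta_s=0.0008, time_step=0.01)
        b = link_patterns(frames, delta_s=0.0008, time_step=0.01)
        assert as_point_lists(a) == as_point_lists(b)

    def test_invalid_delta_s(self):
        with pytest.raises(ValueError):
            link_patterns([], delta_s=0.0, time_step=0.01)


class TestFundamentalFrequency:
    def test_single_point(self):
        frames = frames_from_points([[(0.1, 1.0)]])
        ps = link_patterns(frames, delta_s=0.0008, time_step=0.01)
        assert ps.fm[0] == pytest.approx(10.0)

    def test_mean_of_inverse_scales(self):
        pat = op.Pattern(points=[(0.0, 0.1, 1.0), (0.01, 0.125, 1.0)],
                         time_step=0.01)
        assert op.fundamental_frequency(pat) == pytest.approx(9.0)

    def test_constant_scale_any_length(self):
        pts = [(0.01 * i, 0.025, 1.0) for i in range(50)]
        pat = op.Pattern(points=pts, time_step=0.01)
        assert op.fundamental_frequency(pat) == pytest.approx(40.0)

    def test_nonpositive_scale_rejected(self):
        pat = op.Pattern(points=[(0.0, -0.1, 1.0)], time_step=0.01)
        with pytest.raises(ValueError):
            op.fundamental_frequency(pat)


def make_pattern_set(entries, time_step=0.01):
    """entries: list of (start_idx, n_points, scale)."""
    start, end, fm = [], [], []
    pp, pt, psc, pm = [], [], [], []
    for i, (s0, n, sc) in enumerate(entries):
        start.append(s0)
        end.append(s0 + n - 1)
        fm.append(1.0 / sc)
        for j in range(n):
            pp.append(i)
            pt.append(s0 + j)
            psc.append(sc)
            pm.append(1.0)
    return op.PatternSet(
        np.array(start), np.array(end), np.array(fm),
        np.array(pp), np.array(pt), np.array(psc), np.array(pm),
        time_step=time_step,
    )


class TestNoiseFilter:
    def test_short_pattern_excluded(self):
        # Fm = 10 Hz, T = 0.05 s < 0.1 s
        ps = make_pattern_set([(0, 6, 0.1)], time_step=0.01)
        assert noise_filter(ps).start_idx.size == 0

    def test_long_pattern_retained(self):
        # T = 0.2 s >= 0.1 s
        ps = make_pattern_set([(0, 21, 0.1)], time_step=0.01)
        assert len(noise_filter(ps)) == 1

    def test_boundary_exactly_one_period_retained(self):
        # T = (11-1)*0.01 = 0.1 = 1/Fm exactly
        ps = make_pattern_set([(0, 11, 0.1)], time_step=0.01)
        assert len(noise_filter(ps)) == 1

    def test_all_retained_satisfy_duration_rule(self):
        rng = np.random.default_rng(4)
        entries = [(int(rng.integers(0, 100)), int(rng.integers(1, 40)),
                    float(rng.choice([0.025, 0.05, 0.1, 0.2])))
                   for _ in range(200)]
        ps = make_pattern_set(entries, time_step=0.005)
        kept = noise_filter(ps)
        assert np.all(kept.duration >= 1.0 / kept.fm)
        # order preserved
        assert np.all(np.diff(kept.start_idx[np.argsort(kept.start_idx,
                                                        kind="stable")]) >= 0)


class TestNormalizeToEpochs:
    def test_uniform_patterns_mean_two_per_epoch(self):
        entries = [(int(i * 15.0 / 0.01), 30, 0.1) for i in range(6)]
        ps = make_pattern_set(entries, time_step=0.01)
        tab = normalize_to_epochs(ps, record_length=90.0, epoch_seconds=30.0)
        assert len(tab) == 3
        assert tab["count"].mean() == pytest.approx(2.0)

    def test_zero_patterns_counts_zero_duration_missing(self):
        ps = make_pattern_set([], time_step=0.01)
        tab = normalize_to_epochs(ps, record_length=60.0, epoch_seconds=30.0)
        assert (tab["count"] == 0).all()
        assert tab["t_mean"].isna().all()

    def test_pattern_assigned_by_start_time_only(self):
        # t_start = 29.9 s, t_end = 31 s -> epoch 0 only
        ps = make_pattern_set([(2990, 111, 0.1)], time_step=0.01)
        tab = normalize_to_epochs(ps, record_length=60.0, epoch_seconds=30.0)
        assert tab.loc[tab.epoch_index == 0, "count"].item() == 1
        assert tab.loc[tab.epoch_index == 1, "count"].item() == 0

    def test_epoch_boundary_tie_goes_to_later_epoch(self):
        ps = make_pattern_set([(3000, 50, 0.1)], time_step=0.01)
        tab = normalize_to_epochs(ps, record_length=60.0, epoch_seconds=30.0)
        assert tab.loc[tab.epoch_index == 1, "count"].item() == 1

    def test_partial_final_epoch_dropped(self):
        ps = make_pattern_set([(100, 30, 0.1), (6500, 30, 0.1)],
                              time_step=0.01)
        tab = normalize_to_epochs(ps, record_length=70.0, epoch_seconds=30.0)
        assert len(tab) == 2  # 70 s -> 2 complete epochs
        assert tab["count"].sum() == 1  # the 65-s pattern is discarded

    def test_invalid_epoch_seconds(self):
        ps = make_pattern_set([], time_step=0.01)
        with pytest.raises(ValueError):
            normalize_to_epochs(ps, 60.0, epoch_seconds=0.0)

    def test_split_concat_consistency(self):
        """Patterns interior to each half give the same per-part counts as
        the whole record."""
        rng = np.random.default_rng(12)
        entries = [(int(rng.uniform(1, 58) / 0.01), 30, 0.1)
                   for _ in range(40)]
        ps = make_pattern_set(entries, time_step=0.01)
        whole = normalize_to_epochs(ps, 60.0, 30.0)
        first = ps.select(ps.t_start < 30.0)
        second = ps.select(ps.t_start >= 30.0)
        a = normalize_to_epochs(first, 30.0, 30.0)
        shifted = op.PatternSet(
            second.start_idx - 3000, second.end_idx - 3000, second.fm,
            second.pt_pattern, second.pt_time_idx - 3000, second.pt_scale,
            second.pt_modulus, time_step=0.01,
        )
        b = normalize_to_epochs(shifted, 30.0, 30.0)
        assert whole["count"].tolist() == (a["count"].tolist()
                                           + b["count"].tolist())
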