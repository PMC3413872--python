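import numpy as np
import pytest

from cnvsurv.cbs import (CommonRegion, CopyStateCall, Segment, call_states,
                         cbs_segment, derive_common_regions,
                         max_circular_stat)
from cnvsurv.cbs import test_all_regions as region_tests
from cnvsurv.cox import SurvivalData
from conftest import toy_marker_map


def brute_max_arc(y, mw):
    """Exhaustive scan over all valid arcs (independent oracle)."""
    y = np.asarray(y, float)
    n = y.size
    s = np.std(y, ddof=1)
    best = (-np.inf, None, None)
    for k in range(mw, n - mw + 1):
        for i in range(0, n - k + 1):
            r = n - i - k
            if not ((i == 0 or i >= mw) and (r == 0 or r >= mw)):
                continue
            arc = y[i:i + k]
            comp = np.concatenate([y[:i], y[i + k:]])
            t = abs(arc.mean() - comp.mean()) / (s * np.sqrt(1 / k + 1 / (n - k)))
            if t > best[0]:
                best = (t, i, i + k)
    return best


class TestMaxCircularStat:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 30))
        mw = int(rng.integers(1, 4))
        y = rng.normal(size=n)
        t, i, j = max_circular_stat(y, mw)
        tb, ib, jb = brute_max_arc(y, mw)
        assert t == pytest.approx(tb, abs=1e-9)
        # the split boundaries must agree up to arc/complement symmetry
        assert ({i, j} - {0, n}) == ({ib, jb} - {0, n})

    def test_constant_profile_zero(self):
        assert max_circular_stat(np.ones(10), 3)[0] == 0.0

    def test_clean_step_boundary(self):
        y = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        t, i, j = max_circular_stat(y, 3)
        assert {i, j} - {0, 20} == {10}

    def test_reversal_symmetry(self):
        y = np.random.default_rng(7).normal(size=24)
        assert max_circular_stat(y, 3)[0] == pytest.approx(
            max_circular_stat(y[::-1], 3)[0])

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            max_circular_stat(np.arange(5), 3)


class TestCbsSegment:
    def _run(self, y, seed=1, **kw):
        pos = np.arange(y.size) * 1000 + 1
        return cbs_segment(y, pos, "s0", "1", rng=np.random.default_rng(seed),
                           **kw)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            self._run(np.zeros(10), alpha=0.0)
        with pytest.raises(ValueError):
            self._run(np.zeros(10), n_perm=0)
        with pytest.raises(ValueError, match="finite"):
            self._run(np.array([1.0, np.nan, 0.0] * 4))

    def test_constant_input_single_segment(self):
        segs = self._run(np.full(50, 1.5))
        assert len(segs) == 1
        assert segs[0].n_markers == 50 and segs[0].seg_mean == 1.5

    def test_segments_partition_markers(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(4, 1, 30),
                            rng.normal(0, 1, 30)])
        segs = self._run(y)
        bounds = sorted((s.start_idx, s.end_idx) for s in segs)
        assert bounds[0][0] == 0 and bounds[-1][1] == 100
        for (a1, b1), (a2, b2) in zip(bounds, bounds[1:]):
            assert b1 == a2  # contiguous, no overlap
        assert sum(s.n_markers for s in segs) == 100

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=60)
        s1 = self._run(y, seed=5)
        s2 = self._run(y, seed=5)
        assert [(s.start_idx, s.end_idx, s.seg_mean) for s in s1] == \
               [(s.start_idx, s.end_idx, s.seg_mean) for s in s2]

    def test_two_marker_aberration_not_emitted(self):
        y = np.zeros(30)
        y[14:16] = 5.0  # extreme but below the three-marker minimum
        rng = np.random.default_rng(3)
        y += rng.normal(0, 0.1, 30)
        segs = self._run(y, min_width=3)
        assert all(s.n_markers >= 3 for s in segs)

    def test_planted_step_found(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        segs = self._run(y)
        boundaries = {s.start_idx for s in segs} - {0}
        assert any(abs(b - 50) <= 1 for b in boundaries)


def _seg(mean, sample="s0", chrom="1", start=0, width=5):
    return Segment(sample_id=sample, chrom=chrom, start_idx=start,
                   end_idx=start + width, start_bp=start * 1000 + 1,
                   end_bp=(start + width - 1) * 1000 + 1, n_markers=width,
                   seg_mean=mean)


class TestCallStates:
    def test_identical_means_all_normal(self):
        calls = call_states([_seg(0.5, start=5 * i) for i in range(10)])
        assert all(c.state == 0 for c in calls)

    def test_single_extreme_low_is_the_only_loss(self):
        segs = [_seg(-10.0)] + [_seg(0.0, start=5 * (i + 1)) for i in range(99)]
        calls = call_states(segs)
        states = [c.state for c in calls]
        assert states[0] == -1
        assert all(s == 0 for s in states[1:])

    def test_states_in_three_level_set(self):
        rng = np.random.default_rng(1)
        segs = [_seg(m, start=5 * i) for i, m in
                enumerate(rng.normal(0, 1, 40))]
        for c in call_states(segs):
            assert c.state in (-1, 0, 1)

    def test_weighted_percentile_variant_runs(self):
        segs = [_seg(-2.0, width=3), _seg(0.0, start=3, width=50),
                _seg(2.0, start=53, width=3)]
        calls = call_states(segs, weighted=True)
        assert calls[0].state == -1 and calls[2].state == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            call_states([])


def _make_calls(mm, spec):
    """spec: {sample: [(start, end, state), ...]} covering all markers."""
    out = {}
    n = len(mm)
    for sid, segs in spec.items():
        covered = []
        calls = []
        for a, b, st in segs:
            calls.append(CopyStateCall(
                Segment(sample_id=sid, chrom="1", start_idx=a, end_idx=b,
                        start_bp=int(mm.pos_bp[a]),
                        end_bp=int(mm.pos_bp[b - 1]), n_markers=b - a,
                        seg_mean=float(st)), st))
            covered.append((a, b))
        assert sorted(covered)[0][0] == 0 and sorted(covered)[-1][1] == n
        out[sid] = calls
    return out


class TestCommonRegions:
    def test_recurrence_threshold_unmet(self):
        mm = toy_marker_map(100)
        spec = {f"s{i}": [(0, 40, 0), (40, 60, -1), (60, 100, 0)]
                for i in range(4)}
        spec.update({f"n{i}": [(0, 100, 0)] for i in range(6)})
        regions = derive_common_regions(_make_calls(mm, spec), mm,
                                        recurrence=5)
        assert regions == []

    def test_staggered_losses_yield_coverage_run(self):
        mm = toy_marker_map(100)
        # six samples whose losses all overlap on markers 40..60
        spec = {}
        for i in range(6):
            a, b = 40 - 2 * i, 60 + 2 * i
            spec[f"s{i}"] = [(0, a, 0), (a, b, -1), (b, 100, 0)]
        spec.update({f"n{i}": [(0, 100, 0)] for i in range(4)})
        regions = derive_common_regions(_make_calls(mm, spec), mm,
                                        recurrence=5)
        assert len(regions) == 1
        r = regions[0]
        # sweep-line oracle: marker coverage >= 5 exactly on [38, 62)
        assert (r.start_idx, r.end_idx) == (38, 62)
        assert r.sign == -1
        assert r.n_loss == 6 and r.n_normal == 4
        assert r.n_gain + r.n_normal + r.n_loss == 10

    def test_abutting_runs_merge_by_maximality(self):
        mm = toy_marker_map(60)
        spec = {}
        for i in range(5):
            spec[f"a{i}"] = [(0, 10, 0), (10, 20, -1), (20, 60, 0)]
            spec[f"b{i}"] = [(0, 20, 0), (20, 30, -1), (30, 60, 0)]
        regions = derive_common_regions(_make_calls(mm, spec), mm,
                                        recurrence=5)
        assert len(regions) == 1
        assert (regions[0].start_idx, regions[0].end_idx) == (10, 30)

    def test_majority_rule_ties_resolve_to_normal(self):
        mm = toy_marker_map(20)
        # sample t's loss covers exactly half the region's markers
        spec = {f"s{i}": [(0, 20, -1)] for i in range(5)}
        spec["t"] = [(0, 10, -1), (10, 20, 0)]
        regions = derive_common_regions(_make_calls(mm, spec), mm,
                                        recurrence=5)
        assert len(regions) == 1
        st = dict(zip(spec.keys(), regions[0].states))
        assert st["t"] == 0 and st["s0"] == -1


class TestRegionTests:
    def _survival(self, n, rng):
        T = rng.exponential(100, n)
        return SurvivalData(np.zeros(n), T, np.ones(n, int),
                            rng.normal(size=(n, 1)))

    def _region(self, states):
        return CommonRegion(chrom="1", start_idx=0, end_idx=5, start_bp=1,
                            end_bp=5000, sign=-1,
                            states=np.asarray(states, np.int8), n_markers=5)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        n = 80
        d = self._survival(n, rng)
        regions = [self._region(rng.choice([-1, 0], n)) for _ in range(20)]
        results = region_tests(regions, d)
        m = sum(r.testable for r in results)
        assert m == 20
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, m * r.p))

    def test_untestable_region_excluded_from_m(self):
        rng = np.random.default_rng(1)
        n = 50
        d = self._survival(n, rng)
        regions = [self._region(rng.choice([-1, 0], n)),
                   self._region(np.zeros(n))]
        results = region_tests(regions, d)
        assert results[0].testable and not results[1].testable
        assert results[0].n_tests == 1
        assert results[0].p_bonferroni == pytest.approx(results[0].p)
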