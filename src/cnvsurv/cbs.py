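"""Circular binary segmentation of normalized intensities and region tests.

Per sample and chromosome, the Z profile is recursively partitioned at the
arc maximizing the circular two-sample statistic

    T = max over arcs (i, j] of |mean(arc) - mean(rest)| / (s * sqrt(1/k + 1/(n-k)))

with ``s`` the overall standard deviation of the profile.  Split
significance is assessed by a permutation test; splits honour a minimum
segment width (three markers by default).  Segment means are then
classified per sample against the sample's own 3rd/97th percentile of
segment means (loss / gain), recurrent alterations across samples define
common CNV regions, and each region is tested against survival with a
left-truncated Cox trend model, Bonferroni-corrected over tested regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .cox import (NonIdentifiableError, SurvivalData, test_categorical_2df,
                  test_trend)

logger = logging.getLogger(__name__)

__all__ = [
    "Segment", "CopyStateCall", "CommonRegion", "RegionTestResult",
    "max_circular_stat", "cbs_segment", "call_states",
    "derive_common_regions", "test_all_regions", "segment_cohort",
]


@dataclass(frozen=True)
class Segment:
    """A constant-copy run of markers for one sample on one chromosome.

    Marker indices are 0-based half-open within the chromosome; bp bounds
    are the closed interval spanned by the member markers.
    """

    sample_id: str
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_markers: int
    seg_mean: float

    def __post_init__(self):
        if self.n_markers < 1 or self.end_idx - self.start_idx != self.n_markers:
            raise ValueError("segment must span >= 1 marker")


@dataclass(frozen=True)
class CopyStateCall:
    segment: Segment
    state: int  # -1 loss, 0 normal, +1 gain

    def __post_init__(self):
        if self.state not in (-1, 0, 1):
            raise ValueError("state must be -1, 0 or +1")


@dataclass
class CommonRegion:
    chrom: str
    start_idx: int  # chromosome-local marker index range, half-open
    end_idx: int
    start_bp: int
    end_bp: int
    sign: int  # +1 recurrent gain run, -1 recurrent loss run
    states: np.ndarray  # per-sample majority state over the region
    n_markers: int

    @property
    def n_gain(self):
        return int(np.sum(self.states == 1))

    @property
    def n_normal(self):
        return int(np.sum(self.states == 0))

    @property
    def n_loss(self):
        return int(np.sum(self.states == -1))

    @property
    def label(self):
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


@dataclass
class RegionTestResult:
    label: str
    chrom: str
    start_bp: int
    end_bp: int
    n_gain: int
    n_normal: int
    n_loss: int
    hr: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    p: float = np.nan
    p_2df: float = np.nan
    p_bonferroni: float = np.nan
    testable: bool = True
    n_tests: int = 0


@lru_cache(maxsize=256)
def _arc_table(n, min_width):
    """Flat table of valid arcs (i, j] for a profile of length n.

    A valid arc leaves every induced piece at least ``min_width`` markers
    wide: arc length k in [min_width, n - min_width] and flanks either
    empty or >= min_width.  Returns (i, j, weight) with weight the
    reciprocal of sqrt(1/k + 1/(n-k)).
    """
    iis, jjs = [], []
    for k in range(min_width, n - min_width + 1):
        for i in range(0, n - k + 1):
            right = n - i - k
            if (i == 0 or i >= min_width) and (right == 0 or right >= min_width):
                iis.append(i)
                jjs.append(i + k)
    i = np.asarray(iis, dtype=np.intp)
    j = np.asarray(jjs, dtype=np.intp)
    k = (j - i).astype(float)
    w = 1.0 / np.sqrt(1.0 / k + 1.0 / (n - k))
    return i, j, k, w


_CHUNK_ELEMS = 1 << 22  # bound memory of the (batch x arcs) stat matrix


def _max_arc_stats(S, tot, n, s, min_width, argmax=False):
    """Row-wise maximal arc statistic for cumulative-sum rows ``S``.

    ``S`` has shape (B, n+1).  With ``argmax=True`` also returns the
    flat-table index of the best arc of row 0.
    """
    i, j, k, w = _arc_table(n, min_width)
    if i.size == 0:
        return (np.zeros(S.shape[0]), -1) if argmax else np.zeros(S.shape[0])
    B = S.shape[0]
    best = np.full(B, -np.inf)
    best_idx = -1
    step = max(1, _CHUNK_ELEMS // max(B, 1))
    for a in range(0, i.size, step):
        sl = slice(a, a + step)
        arc = S[:, j[sl]] - S[:, i[sl]]
        diff = arc / k[sl] - (tot[:, None] - arc) / (n - k[sl])
        stat = np.abs(diff) * (w[sl] / s)
        if argmax:
            m = int(np.argmax(stat[0]))
            if stat[0, m] > best[0]:
                best_idx = a + m
        np.maximum(best, stat.max(axis=1), out=best)
    return (best, best_idx) if argmax else best


def max_circular_stat(y, min_width: int = 1):
    """Maximal circular two-sample statistic and its arc (i, j].

    Raises ValueError("too short") when the profile cannot host a valid
    arc (length < 2 * min_width).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * min_width or n < 2:
        raise ValueError("too short")
    s = float(np.std(y, ddof=1))
    if s == 0.0:
        return 0.0, 0, min_width
    S = np.concatenate([[0.0], np.cumsum(y)])[None, :]
    tot = S[:, -1]
    best, idx = _max_arc_stats(S, tot, n, s, min_width, argmax=True)
    if idx < 0:
        raise ValueError("too short")
    i, j, _, _ = _arc_table(n, min_width)
    return float(best[0]), int(i[idx]), int(j[idx])


def _perm_max_stats(y, s, min_width, n_draw, rng):
    """Max arc statistic for ``n_draw`` random permutations of y."""
    Y = np.tile(y, (n_draw, 1))
    Y = rng.permuted(Y, axis=1)
    S = np.concatenate([np.zeros((n_draw, 1)), np.cumsum(Y, axis=1)], axis=1)
    tot = S[:, -1]
    return _max_arc_stats(S, tot, y.size, s, min_width)


_BATCHES = (48, 208, 744)  # escalating draws; clearly-null splits stop early


def _split_pvalue(y, t_obs, s, min_width, alpha, n_perm, rng):
    """Permutation p-value with deterministic early stopping.

    Shuffles are drawn in escalating batches; once the exceedance count
    already guarantees p > alpha at the nominal ``n_perm`` the remaining
    shuffles cannot change the split decision and are skipped.  The
    returned p is the proportion of drawn shuffles meeting or exceeding
    the observed statistic.
    """
    limit = int(np.floor(alpha * n_perm))
    count = 0
    drawn = 0
    b = 0
    while drawn < n_perm:
        nb = min(_BATCHES[min(b, len(_BATCHES) - 1)], n_perm - drawn)
        b += 1
        stats = _perm_max_stats(y, s, min_width, nb, rng)
        count += int(np.sum(stats >= t_obs))
        drawn += nb
        if count > limit:
            return count / drawn
    return count / n_perm


def _segment_indices(y, alpha, n_perm, min_width, rng):
    n = y.size
    if n < 2 * min_width:
        return [(0, n)]
    s = float(np.std(y, ddof=1))
    if s == 0.0:
        return [(0, n)]
    t_obs, i, j = max_circular_stat(y, min_width=min_width)
    if not np.isfinite(t_obs) or t_obs <= 0:
        return [(0, n)]
    p = _split_pvalue(y, t_obs, s, min_width, alpha, n_perm, rng)
    if p > alpha:
        return [(0, n)]
    pieces = [(0, i), (i, j), (j, n)]
    out = []
    for lo, hi in pieces:
        if hi <= lo:
            continue
        sub = _segment_indices(y[lo:hi], alpha, n_perm, min_width, rng)
        out.extend((lo + a, lo + b) for a, b in sub)
    return out


def cbs_segment(y, pos_bp, sample_id: str, chrom: str, alpha: float = 0.01,
                n_perm: int = 1000, min_width: int = 3, rng=None):
    """Segment one sample's chromosome profile into Segment objects.

    Recursive circular binary segmentation: the maximal-arc statistic is
    tested by permutation (``p = proportion of shuffles with max stat >=
    observed``); a split is accepted when p <= alpha and every resulting
    piece spans at least ``min_width`` markers.  Deterministic given the
    random generator / seed.
    """
    if alpha <= 0 or n_perm <= 0:
        raise ValueError("alpha and n_perm must be positive")
    y = np.asarray(y, dtype=float)
    pos_bp = np.asarray(pos_bp)
    if y.size != pos_bp.size:
        raise ValueError("profile and positions differ in length")
    if not np.isfinite(y).all():
        raise ValueError("profile must be finite")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    bounds = _segment_indices(y, alpha, n_perm, min_width, rng)
    segs = []
    for lo, hi in bounds:
        segs.append(Segment(
            sample_id=sample_id, chrom=chrom, start_idx=lo, end_idx=hi,
            start_bp=int(pos_bp[lo]), end_bp=int(pos_bp[hi - 1]),
            n_markers=hi - lo, seg_mean=float(y[lo:hi].mean()),
        ))
    return segs


def _weighted_percentile(values, weights, q):
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order], dtype=float)
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, q / 100.0, side="left"))
    return v[min(idx, v.size - 1)]


def call_states(segments, lower_pct: float = 3.0, upper_pct: float = 97.0,
                weighted: bool = False):
    """Classify one sample's segments as loss / normal / gain.

    Thresholds are the sample's own percentiles of its segment means
    (unweighted by default; ``weighted=True`` weights by marker count).
    A segment is a loss when its mean is at or below the lower threshold
    while strictly below the upper one, and symmetrically for gains;
    degenerate percentile ties therefore resolve to normal.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    means = np.array([s.seg_mean for s in segments])
    if weighted:
        w = np.array([s.n_markers for s in segments], dtype=float)
        lo = _weighted_percentile(means, w, lower_pct)
        hi = _weighted_percentile(means, w, upper_pct)
    else:
        lo = np.percentile(means, lower_pct)
        hi = np.percentile(means, upper_pct)
    calls = []
    for seg, m in zip(segments, means):
        if m <= lo and m < hi:
            state = -1
        elif m >= hi and m > lo:
            state = 1
        else:
            state = 0
        calls.append(CopyStateCall(segment=seg, state=state))
    return calls


def segment_cohort(Z, marker_map, sample_ids, alpha: float = 0.01,
                   n_perm: int = 1000, min_width: int = 3,
                   lower_pct: float = 3.0, upper_pct: float = 97.0,
                   weighted: bool = False, seed=None):
    """CBS + state calling for every sample; returns calls per sample.

    Segmentation runs per chromosome; state thresholds are per sample over
    that sample's genome-wide segment means.
    """
    rng = np.random.default_rng(seed)
    chrom_arr = marker_map.chrom
    pos = marker_map.pos_bp
    chrom_slices = [(c, np.nonzero(chrom_arr == c)[0])
                    for c in marker_map.chromosomes()]
    calls_by_sample = {}
    for si, sid in enumerate(sample_ids):
        segs = []
        for c, idx in chrom_slices:
            segs.extend(cbs_segment(
                Z[si, idx], pos[idx], sample_id=sid, chrom=c,
                alpha=alpha, n_perm=n_perm, min_width=min_width, rng=rng))
        calls_by_sample[sid] = call_states(
            segs, lower_pct=lower_pct, upper_pct=upper_pct, weighted=weighted)
    return calls_by_sample


def _state_tracks(calls_by_sample, marker_map):
    """Per-sample, per-marker state matrix from segment calls."""
    chrom_arr = marker_map.chrom
    chroms = marker_map.chromosomes()
    offsets = {c: int(np.nonzero(chrom_arr == c)[0][0]) for c in chroms}
    sample_ids = list(calls_by_sample)
    states = np.zeros((len(sample_ids), len(marker_map)), dtype=np.int8)
    for si, sid in enumerate(sample_ids):
        for call in calls_by_sample[sid]:
            off = offsets[call.segment.chrom]
            states[si, off + call.segment.start_idx:
                   off + call.segment.end_idx] = call.state
    return sample_ids, states


def derive_common_regions(calls_by_sample, marker_map, recurrence: int = 5):
    """Marker-resolution sweep for recurrent gain/loss regions.

    For each sign separately, maximal runs of markers at which at least
    ``recurrence`` samples carry that state become a CommonRegion; runs
    of the same sign with no intervening markers are merged by maximality.
    Each sample's state within a region is its majority state over the
    region's markers (ties resolve to normal).
    """
    sample_ids, states = _state_tracks(calls_by_sample, marker_map)
    chrom_arr = marker_map.chrom
    pos = marker_map.pos_bp
    regions = []
    for c in marker_map.chromosomes():
        mask = chrom_arr == c
        idx = np.nonzero(mask)[0]
        sub = states[:, mask]
        for sign in (1, -1):
            counts = np.sum(sub == sign, axis=0)
            qual = counts >= recurrence
            if not qual.any():
                continue
            d = np.diff(np.concatenate([[0], qual.astype(int), [0]]))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            for a, b in zip(starts, ends):
                reg = sub[:, a:b]
                n_loss = np.sum(reg == -1, axis=1)
                n_gain = np.sum(reg == 1, axis=1)
                n_norm = (b - a) - n_loss - n_gain
                st = np.zeros(len(sample_ids), dtype=np.int8)
                st[(n_loss > n_norm) & (n_loss > n_gain)] = -1
                st[(n_gain > n_norm) & (n_gain > n_loss)] = 1
                regions.append(CommonRegion(
                    chrom=c, start_idx=int(a), end_idx=int(b),
                    start_bp=int(pos[idx[a]]), end_bp=int(pos[idx[b - 1]]),
                    sign=sign, states=st, n_markers=int(b - a),
                ))
    return regions


def test_all_regions(regions, survival: SurvivalData, with_2df: bool = True):
    """Trend test per common region, Bonferroni over tested regions.

    Regions with fewer than two state levels are reported untestable and
    excluded from the Bonferroni count m; p_bonferroni = min(1, m * p).
    """
    results = []
    testable_idx = []
    for r in regions:
        res = RegionTestResult(
            label=r.label, chrom=r.chrom, start_bp=r.start_bp,
            end_bp=r.end_bp, n_gain=r.n_gain, n_normal=r.n_normal,
            n_loss=r.n_loss)
        try:
            fit, p = test_trend(r.states, survival)
        except NonIdentifiableError:
            res.testable = False
            results.append(res)
            continue
        res.hr = float(fit.hr[0])
        res.ci95 = (float(fit.ci95[0, 0]), float(fit.ci95[0, 1]))
        res.p = p
        if with_2df:
            try:
                _, p2, _ = test_categorical_2df(r.states, survival)
                res.p_2df = p2
            except NonIdentifiableError:
                pass
        results.append(res)
        testable_idx.append(len(results) - 1)
    m = len(testable_idx)
    for i in testable_idx:
        results[i].n_tests = m
        if np.isfinite(results[i].p):
            results[i].p_bonferroni = min(1.0, m * results[i].p)
    return results
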