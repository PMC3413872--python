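"""Single-marker survival scan with fused-lasso smoothing (approach 1).

Each marker's centered intensity Z is tested against survival with a
left-truncated Cox model; the resulting -log10 p profile is smoothed per
chromosome with a fused-lasso signal approximator

    f = argmin 1/2 sum (y_t - f_t)^2 + lam1 sum |f_t| + lam2 sum |f_{t+1} - f_t|

solved exactly (direct 1-D total-variation algorithm, then
soft-thresholding for the sparsity term).  Maximal runs of markers whose
smoothed value exceeds a threshold (default 2, i.e. smoothed p < 0.01)
become regions of interest; within each, per-sample local segmentation
assigns loss/normal/gain states that are then tested for association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cox import (NonIdentifiableError, SurvivalData, fit_cox_left_truncated,
                  test_categorical_2df, test_trend)
from .cbs import RegionTestResult

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerScanResult", "SmoothedProfile", "RegionOfInterest", "RoiStateCall",
    "scan_markers", "tv_denoise", "flsa_smooth", "select_lambda_fuse",
    "detect_roi", "refine_roi", "associate_roi",
]


@dataclass
class MarkerScanResult:
    """Per-marker Cox scan output aligned to the marker map order."""

    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    skipped: np.ndarray  # bool
    skip_reason: np.ndarray  # object

    @property
    def neglog10p(self):
        with np.errstate(divide="ignore"):
            v = -np.log10(self.p)
        return np.where(self.skipped, np.nan, v)


@dataclass
class SmoothedProfile:
    chrom: str
    f: np.ndarray
    lambda_fuse: float
    lambda_sparse: float
    marker_idx: np.ndarray  # global indices of the (non-skipped) markers

    def __post_init__(self):
        if not np.isfinite(self.f).all():
            raise ValueError("smoothed profile must be finite")


@dataclass
class RegionOfInterest:
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    peak_smoothed: float
    peak_marker_id: str
    marker_idx: np.ndarray  # global marker indices of members


@dataclass
class RoiStateCall:
    sample_id: str
    state: int  # -1, 0, +1
    seg_mean: float
    n_markers: int

    def __post_init__(self):
        if self.state not in (-1, 0, 1):
            raise ValueError("state must be -1, 0 or +1")


def scan_markers(Z, marker_map, survival: SurvivalData,
                 var_min: float = 1e-12) -> MarkerScanResult:
    """One left-truncated Cox fit per marker with Z as the tested covariate.

    Near-constant markers are skipped with a reason; fit failures are
    recorded per marker and the scan continues.
    """
    n, m = Z.shape
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    skipped = np.zeros(m, dtype=bool)
    reason = np.full(m, "", dtype=object)
    for j in range(m):
        z = Z[:, j]
        if np.var(z) < var_min:
            skipped[j] = True
            reason[j] = "constant"
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox_left_truncated(survival.with_tested(z, "Z"))
        except (NonIdentifiableError, np.linalg.LinAlgError) as e:
            skipped[j] = True
            reason[j] = f"fit_failed: {e}"
            continue
        if not np.isfinite(fit.p_wald[0]):
            skipped[j] = True
            reason[j] = "separation"
            continue
        beta[j], se[j], p[j] = fit.beta[0], fit.se[0], fit.p_wald[0]
    return MarkerScanResult(
        marker_ids=np.asarray(marker_map.marker_ids),
        chrom=np.asarray(marker_map.chrom),
        pos_bp=np.asarray(marker_map.pos_bp),
        beta=beta, se=se, p=p, skipped=skipped, skip_reason=reason,
    )


def tv_denoise(y, lam: float):
    """Exact 1-D total-variation denoising (direct non-iterative algorithm).

    Solves argmin_f 1/2 sum (y_t - f_t)^2 + lam * sum |f_{t+1} - f_t|.
    """
    y = np.asarray(y, dtype=float)
    N = y.size
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if N == 0 or lam == 0:
        return y.copy()
    x = np.empty(N)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == N - 1:
            if umin < 0:
                x[k0:km + 1] = vmin
                km += 1
                k = k0 = km
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            if umax > 0:
                x[k0:kp + 1] = vmax
                kp += 1
                k = k0 = kp
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            x[k0:N] = vmin + umin / (k - k0 + 1)
            return x
        if y[k + 1] + umin < vmin - lam:      # negative jump: flush at vmin
            x[k0:km + 1] = vmin
            km += 1
            k = k0 = kp = km
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:    # positive jump: flush at vmax
            x[k0:kp + 1] = vmax
            kp += 1
            k = k0 = km = kp
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:                                  # no jump: extend the segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


def flsa_smooth(y, lambda_fuse: float, lambda_sparse: float = 0.0,
                chrom: str = "", marker_idx=None) -> SmoothedProfile:
    """Exact fused-lasso signal approximation of a -log10 p profile.

    The fusion term is solved by direct TV denoising; the sparsity term is
    then applied by soft-thresholding, which yields the exact joint
    minimizer in the 1-D fused-lasso problem.
    """
    if lambda_fuse < 0 or lambda_sparse < 0:
        raise ValueError("penalties must be non-negative")
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("profile must be finite (drop skipped markers first)")
    f = tv_denoise(y, lambda_fuse)
    if lambda_sparse > 0:
        f = np.sign(f) * np.maximum(np.abs(f) - lambda_sparse, 0.0)
    if marker_idx is None:
        marker_idx = np.arange(y.size)
    return SmoothedProfile(chrom=chrom, f=f, lambda_fuse=lambda_fuse,
                           lambda_sparse=lambda_sparse,
                           marker_idx=np.asarray(marker_idx))


def select_lambda_fuse(y, grid=None):
    """Smallest penalty on a log grid giving <= sqrt(len(y)) distinct levels.

    The cited smoothing tools tune their penalty internally; this package
    uses a parsimony rule ("piecewise-constant with at most sqrt(m)
    levels") as its own documented convention, overridable by passing an
    explicit penalty.
    """
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.geomspace(0.01, 100.0, 25)
    target = np.sqrt(y.size)
    for lam in grid:
        f = tv_denoise(y, lam)
        n_levels = 1 + int(np.sum(np.abs(np.diff(f)) > 1e-9))
        if n_levels <= target:
            return float(lam)
    return float(grid[-1])


def detect_roi(profiles, marker_map, threshold: float = 2.0):
    """Maximal runs of consecutive markers with smoothed value > threshold."""
    out = []
    marker_ids = np.asarray(marker_map.marker_ids)
    pos = np.asarray(marker_map.pos_bp)
    for prof in profiles:
        above = prof.f > threshold
        if not above.any():
            continue
        d = np.diff(np.concatenate([[0], above.astype(int), [0]]))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for a, b in zip(starts, ends):
            gidx = prof.marker_idx[a:b]
            peak_local = a + int(np.argmax(prof.f[a:b]))
            out.append(RegionOfInterest(
                chrom=prof.chrom,
                start_bp=int(pos[gidx[0]]), end_bp=int(pos[gidx[-1]]),
                n_markers=int(b - a),
                peak_smoothed=float(prof.f[peak_local]),
                peak_marker_id=str(marker_ids[prof.marker_idx[peak_local]]),
                marker_idx=gidx,
            ))
    return out


def _tstat_splits(y, min_markers, p_thresh, snr):
    """Best accepted two-sample t-test split of y, or None.

    A split at t partitions y into y[:t], y[t:]; it is accepted when the
    two-sample t-test p-value is below ``p_thresh``, the standardized mean
    difference |mean1 - mean2| / pooled SD is at least ``snr``, and both
    sides span >= ``min_markers``.
    """
    n = y.size
    best = None
    best_p = p_thresh
    for t in range(min_markers, n - min_markers + 1):
        a, b = y[:t], y[t:]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        pooled = np.sqrt(((t - 1) * va + (n - t - 1) * vb) / (n - 2))
        if pooled == 0:
            pooled = 1e-12
        diff = abs(a.mean() - b.mean())
        if diff / pooled < snr:
            continue
        tval = diff / (pooled * np.sqrt(1.0 / t + 1.0 / (n - t)))
        p = 2.0 * sps.t.sf(tval, n - 2)
        if p < best_p:
            best_p = p
            best = t
    return best


def _recursive_tsplit(y, min_markers, p_thresh, snr):
    if y.size < 2 * min_markers:
        return [(0, y.size)]
    t = _tstat_splits(y, min_markers, p_thresh, snr)
    if t is None:
        return [(0, y.size)]
    left = _recursive_tsplit(y[:t], min_markers, p_thresh, snr)
    right = _recursive_tsplit(y[t:], min_markers, p_thresh, snr)
    return left + [(t + a, t + b) for a, b in right]


def refine_roi(Z_window, sample_ids, min_markers: int = 5,
               p_thresh: float = 0.001, snr: float = 0.3,
               below: float = -0.3, above: float = 0.15):
    """Per-sample local segmentation and state assignment inside a window.

    Candidate segments come from recursive binary segmentation of each
    sample's Z with a two-sample t-test split criterion (split accepted
    when p < p_thresh, |mean difference| / pooled SD >= snr, and each side
    spans >= min_markers).  A sample is called a loss when its lowest
    candidate segment mean is at or below ``below``, a gain when its
    highest is at or above ``above``, else normal.  This local segmenter
    realizes the documented parameter semantics of the proprietary tool
    it stands in for.
    """
    Z_window = np.atleast_2d(np.asarray(Z_window, dtype=float))
    n, m = Z_window.shape
    if m < min_markers:
        warnings.warn(
            f"window has {m} markers (< {min_markers}); no calls made",
            stacklevel=2)
        return []
    calls = []
    for i, sid in enumerate(sample_ids):
        y = Z_window[i]
        segs = _recursive_tsplit(y, min_markers, p_thresh, snr)
        means = np.array([y[a:b].mean() for a, b in segs])
        widths = np.array([b - a for a, b in segs])
        lo_idx = int(np.argmin(means))
        hi_idx = int(np.argmax(means))
        if means[lo_idx] <= below:
            state, mean, w = -1, means[lo_idx], widths[lo_idx]
        elif means[hi_idx] >= above:
            state, mean, w = 1, means[hi_idx], widths[hi_idx]
        else:
            # report the most extreme candidate as support
            k = lo_idx if abs(means[lo_idx]) >= abs(means[hi_idx]) else hi_idx
            state, mean, w = 0, means[k], widths[k]
        calls.append(RoiStateCall(sample_id=sid, state=state,
                                  seg_mean=float(mean), n_markers=int(w)))
    return calls


def associate_roi(calls, survival: SurvivalData, roi: RegionOfInterest = None):
    """Trend and categorical survival tests of the ROI state calls."""
    states = np.array([c.state for c in calls])
    res = RegionTestResult(
        label=roi.peak_marker_id if roi is not None else "roi",
        chrom=roi.chrom if roi is not None else "",
        start_bp=roi.start_bp if roi is not None else 0,
        end_bp=roi.end_bp if roi is not None else 0,
        n_gain=int(np.sum(states == 1)),
        n_normal=int(np.sum(states == 0)),
        n_loss=int(np.sum(states == -1)),
    )
    try:
        fit, p = test_trend(states, survival)
    except NonIdentifiableError:
        res.testable = False
        return res
    res.hr = float(fit.hr[0])
    res.ci95 = (float(fit.ci95[0, 0]), float(fit.ci95[0, 1]))
    res.p = p
    try:
        _, p2, _ = test_categorical_2df(states, survival)
        res.p_2df = p2
    except NonIdentifiableError:
        pass
    return res
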