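"""Normalization of raw two-channel SNP-array intensities.

The pipeline turns raw allele intensities (A, B) into a subject-centered
log2 total-intensity matrix Z whose deviations from zero indicate copy
gain or loss:

1. Channel balance: for each marker j a correction factor
   ``psi_j = mean(A_ij / B_ij)`` over the K subjects called heterozygous
   equalizes the two dyes, and total intensity is
   ``I_ij = log2(A_ij + psi_j * B_ij)``.
2. Quantile normalization across subjects (identical intensity
   distributions per subject).
3. Median normalization per marker within each plate (removes plate batch
   effects).
4. Subject centering: ``Z_ij = I_ij - mean_j(I_ij)``.

Markers with no usable heterozygotes (intensity-only CNV probes, rare
monomorphic SNPs) fall back to psi = 1, the no-correction identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import IntensityPanel, GT_AB

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionFactors",
    "NormalizedIntensity",
    "allele_correction_factors",
    "total_intensity",
    "quantile_normalize",
    "median_normalize_by_plate",
    "center_within_subject",
    "normalize_pipeline",
]


@dataclass
class CorrectionFactors:
    """Per-marker channel-balance factors psi and heterozygote counts."""

    psi: np.ndarray
    n_hets: np.ndarray
    n_dropped_zero_b: int = 0

    def __post_init__(self):
        if np.any(~np.isfinite(self.psi)) or np.any(self.psi <= 0):
            raise ValueError("psi must be finite and positive")


@dataclass
class NormalizedIntensity:
    """Log2 intensity matrix at a given normalization stage.

    ``missing`` marks (sample, marker) cells whose raw total intensity was
    non-positive; they are median-imputed for quantile normalization and
    stay flagged so downstream code can ignore them.
    """

    I: np.ndarray
    stage: str  # raw_log | quantile | plate_median | centered
    sample_ids: tuple
    marker_ids: tuple
    missing: np.ndarray = None
    subject_means: np.ndarray = None

    def __post_init__(self):
        if self.missing is None:
            self.missing = np.zeros(self.I.shape, dtype=bool)

    @property
    def Z(self):
        if self.stage != "centered":
            raise ValueError("Z is only defined at stage 'centered'")
        return self.I


def allele_correction_factors(panel: IntensityPanel) -> CorrectionFactors:
    """Estimate psi_j = mean over heterozygotes of A/B for every marker.

    Heterozygotes with B = 0 are dropped from the average (their ratio is
    undefined); markers with no usable heterozygotes get psi = 1.
    """
    het = panel.genotype == GT_AB
    usable = het & (panel.B > 0)
    n_zero_b = int((het & ~usable).sum())
    if n_zero_b:
        logger.warning(
            "dropped %d heterozygote(s) with zero B intensity from psi estimation",
            n_zero_b,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(usable, panel.A / np.where(usable, panel.B, 1.0), 0.0)
    k = usable.sum(axis=0)
    psi = np.ones(panel.n_markers)
    has = k > 0
    psi[has] = ratio.sum(axis=0)[has] / k[has]
    n_fallback = int((~has).sum())
    if n_fallback:
        logger.warning("psi fallback to 1 for %d marker(s) with no heterozygotes",
                       n_fallback)
    return CorrectionFactors(psi=psi, n_hets=k, n_dropped_zero_b=n_zero_b)


def total_intensity(panel: IntensityPanel,
                    factors: CorrectionFactors) -> NormalizedIntensity:
    """I_ij = log2(A_ij + psi_j * B_ij); non-positive totals flagged missing."""
    total = panel.A + factors.psi[None, :] * panel.B
    missing = ~(total > 0)
    if missing.any():
        ii, jj = np.nonzero(missing)
        logger.warning(
            "%d non-positive total intensit(ies) flagged missing (first: sample %s, "
            "marker %s)", missing.sum(), panel.sample_ids[ii[0]],
            panel.marker_ids[jj[0]],
        )
    I = np.full(total.shape, np.nan)
    np.log2(total, out=I, where=~missing)
    return NormalizedIntensity(I=I, stage="raw_log",
                               sample_ids=tuple(panel.sample_ids),
                               marker_ids=tuple(panel.marker_ids),
                               missing=missing)


def _impute_marker_median(I, missing):
    if not missing.any():
        return I
    I = I.copy()
    med = np.nanmedian(np.where(missing, np.nan, I), axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    ii, jj = np.nonzero(missing)
    I[ii, jj] = med[jj]
    return I


def quantile_normalize(norm: NormalizedIntensity) -> NormalizedIntensity:
    """Force every subject's intensity distribution to the mean quantile curve.

    Each subject's sorted vector is replaced by the across-subject mean of
    sorted vectors; ties within a subject receive the mean of the pooled
    quantile values they span.  Missing cells are marker-median imputed
    first and re-flagged afterward.
    """
    if norm.stage != "raw_log":
        raise ValueError("quantile normalization expects stage 'raw_log'")
    I = _impute_marker_median(norm.I, norm.missing)
    n, m = I.shape
    if n == 1:
        logger.warning("single-subject input: quantile normalization is identity")
        return NormalizedIntensity(I=I.copy(), stage="quantile",
                                   sample_ids=norm.sample_ids,
                                   marker_ids=norm.marker_ids,
                                   missing=norm.missing.copy())
    order = np.argsort(I, axis=1, kind="stable")
    ref = np.sort(I, axis=1).mean(axis=0)
    out = np.empty_like(I)
    rows = np.arange(n)[:, None]
    out[rows, order] = ref[None, :]
    # tie handling: average the reference values over tied runs per subject
    for i in range(n):
        vals = I[i, order[i]]
        ties = np.nonzero(np.diff(vals) == 0)[0]
        if ties.size:
            # group consecutive tied positions
            start = 0
            srt = out[i, order[i]]
            j = 0
            while j < m - 1:
                if vals[j + 1] == vals[j]:
                    k = j + 1
                    while k < m - 1 and vals[k + 1] == vals[k]:
                        k += 1
                    srt[j:k + 1] = srt[j:k + 1].mean()
                    j = k + 1
                else:
                    j += 1
            out[i, order[i]] = srt
    return NormalizedIntensity(I=out, stage="quantile",
                               sample_ids=norm.sample_ids,
                               marker_ids=norm.marker_ids,
                               missing=norm.missing.copy())


def median_normalize_by_plate(norm: NormalizedIntensity,
                              plates) -> NormalizedIntensity:
    """Subtract the per-(marker, plate) median so each cell's median is 0."""
    if norm.stage != "quantile":
        raise ValueError("plate median normalization expects stage 'quantile'")
    plates = np.asarray(plates)
    if plates.shape[0] != norm.I.shape[0]:
        raise ValueError("one plate assignment per sample required")
    I = norm.I.copy()
    for pl in np.unique(plates):
        mask = plates == pl
        if not mask.any():  # pragma: no cover - unique() precludes this
            logger.warning("plate %s has no samples; ignored", pl)
            continue
        I[mask] -= np.median(I[mask], axis=0)[None, :]
    return NormalizedIntensity(I=I, stage="plate_median",
                               sample_ids=norm.sample_ids,
                               marker_ids=norm.marker_ids,
                               missing=norm.missing.copy())


def center_within_subject(norm: NormalizedIntensity) -> NormalizedIntensity:
    """Z_ij = I_ij - mean over all markers of subject i's intensities."""
    if norm.stage != "plate_median":
        raise ValueError("centering expects stage 'plate_median'")
    means = norm.I.mean(axis=1)
    Z = norm.I - means[:, None]
    return NormalizedIntensity(I=Z, stage="centered",
                               sample_ids=norm.sample_ids,
                               marker_ids=norm.marker_ids,
                               missing=norm.missing.copy(),
                               subject_means=means)


def normalize_pipeline(panel: IntensityPanel, plates):
    """Run psi -> I -> quantile -> plate median -> centering; returns (Z, psi)."""
    factors = allele_correction_factors(panel)
    raw = total_intensity(panel, factors)
    q = quantile_normalize(raw)
    pm = median_normalize_by_plate(q, plates)
    z = center_within_subject(pm)
    return z, factors
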