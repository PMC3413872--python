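"""Synthetic SNP-array cohorts with planted CNVs and survival effects.

The generator emulates the structure of a multi-site genotyping study:

* a marker map over autosomes with SNP and intensity-only (cnv_only)
  probes;
* raw two-channel intensities with per-marker brightness, a per-marker
  channel imbalance (the systematic A/B dye difference the psi correction
  removes), multiplicative log-normal intensity noise, and a per
  (marker, plate) batch effect;
* planted gain/loss regions at specified population frequencies, marker
  widths, and log hazard ratios;
* survival times from an exponential proportional-hazards model with
  delayed entry (cases must survive to enrollment) and administrative
  censoring.

Copy number is capped at 3 (single-copy gain): the analysis pipeline
works with three-level states, so higher amplifications add nothing
testable.  All randomness flows from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GT_AA, GT_AB, GT_BB, GT_NC, IntensityPanel, MarkerMap,
                 SampleManifest)

__all__ = [
    "PlantedRegion", "SimulationConfig", "SyntheticTruth",
    "simulate_marker_map", "simulate_genotypes", "simulate_copy_states",
    "simulate_intensities", "simulate_survival", "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedRegion:
    """A CNV planted in the population.

    ``state`` is -1 (single-copy loss) or +1 (single-copy gain);
    ``frequency`` the carrier probability; ``log_hr`` the per-carrier log
    hazard ratio (0 for a survival-neutral CNV).
    """

    chrom: str
    start_marker: int  # chromosome-local index of the first member marker
    width: int
    state: int
    frequency: float
    log_hr: float = 0.0

    def __post_init__(self):
        if self.state not in (-1, 1):
            raise ValueError("state must be -1 or +1")
        if not 0.0 < self.frequency < 1.0:
            raise ValueError("frequency must be in (0, 1)")
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults are a desk-scale cohort shaped like a three-site ovarian
    cancer study: per-site proportions 1/3, 0.47 and 0.20, enrollment
    within about five months of diagnosis, a death rate near 50% under
    ten-year administrative censoring, and array noise giving a Z
    standard deviation around 0.2.
    """

    n_samples: int = 300
    n_plates: int = 4
    sites: tuple = ("MAY", "NCO", "TBO")
    site_props: tuple = (0.33, 0.47, 0.20)
    n_chrom: int = 4
    markers_per_chrom: int = 500
    spacing_bp: int = 5000
    cnv_only_frac: float = 0.03
    maf_range: tuple = (0.05, 0.5)
    genotype_missing_rate: float = 0.005
    planted_regions: tuple = ()
    sigma: float = 0.15          # multiplicative intensity noise (log scale)
    sigma_plate: float = 0.05    # per (marker, plate) batch effect
    channel_imbalance_sd: float = 0.2
    brightness_sd: float = 0.1
    background: float = 0.05     # epsilon emitted at copy number 0
    baseline_hazard: float = 1.9e-4  # per day; ~50% deaths by 10 years
    censor_days: float = 3650.0
    entry_max_days: float = 160.0
    beta_age: float = 0.02       # log-HR per year of age at diagnosis
    beta_site: tuple = (0.0, 0.1, -0.1)
    beta_pc: float = 0.1
    n_pcs: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.entry_max_days < 0:
            raise ValueError("entry_max_days must be >= 0")
        if self.entry_max_days >= self.censor_days:
            raise ValueError("entry bound must be below the censoring time")
        for r in self.planted_regions:
            if r.start_marker < 0 or r.start_marker + r.width > self.markers_per_chrom:
                raise ValueError(
                    f"planted region exceeds chromosome: {r}")
            if r.chrom not in {str(c + 1) for c in range(self.n_chrom)}:
                raise ValueError(f"planted region on unknown chromosome {r.chrom}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to the synthetic data."""

    carrier: np.ndarray       # (n_samples, n_regions) bool
    regions: tuple            # the PlantedRegion specs
    copy_number: np.ndarray   # (n_samples, n_markers) int
    log_hrs: np.ndarray       # per-region log hazard ratios used
    n_truncation_redraws: int = 0


def simulate_marker_map(config: SimulationConfig, rng) -> MarkerMap:
    rows = []
    for c in range(config.n_chrom):
        chrom = str(c + 1)
        for j in range(config.markers_per_chrom):
            rows.append((f"mk_{chrom}_{j:05d}", chrom,
                         (j + 1) * config.spacing_bp, "snp"))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp",
                                     "probe_class"])
    n_cnv = int(round(config.cnv_only_frac * len(df)))
    if n_cnv:
        idx = rng.choice(len(df), size=n_cnv, replace=False)
        df.loc[idx, "probe_class"] = "cnv_only"
    return MarkerMap(df)


def simulate_copy_states(config: SimulationConfig, marker_map, rng):
    """Draw carriers and build the per-sample copy-number track."""
    n = config.n_samples
    m = len(marker_map)
    regions = tuple(config.planted_regions)
    carrier = np.zeros((n, len(regions)), dtype=bool)
    cn = np.full((n, m), 2, dtype=np.int8)
    chrom_arr = marker_map.chrom
    for k, r in enumerate(regions):
        carrier[:, k] = rng.random(n) < r.frequency
        cidx = np.nonzero(chrom_arr == r.chrom)[0]
        cols = cidx[r.start_marker:r.start_marker + r.width]
        cn[np.ix_(carrier[:, k], cols)] = 2 + r.state
    return carrier, cn


def simulate_genotypes(config: SimulationConfig, marker_map, cn, rng):
    """B-allele dosage b ~ Binomial(c, p_j) and the resulting genotype call.

    SNP probes are called AA/AB/BB from the allele ratio (homozygous-looking
    at copy number 1; heterozygous-looking at 3 unless all alleles agree);
    cnv_only probes are NC everywhere, as are randomly missing calls.
    """
    n, m = cn.shape
    maf = rng.uniform(*config.maf_range, size=m)
    b = rng.binomial(cn.astype(np.int64), maf[None, :]).astype(np.int8)
    gt = np.full((n, m), GT_NC, dtype=np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cn > 0, b / np.maximum(cn, 1), np.nan)
    gt[frac == 0.0] = GT_AA
    gt[frac == 1.0] = GT_BB
    gt[(frac > 0.0) & (frac < 1.0)] = GT_AB
    gt[:, ~marker_map.is_snp] = GT_NC
    if config.genotype_missing_rate > 0:
        miss = rng.random((n, m)) < config.genotype_missing_rate
        gt[miss] = GT_NC
    return gt, b, maf


def simulate_intensities(config: SimulationConfig, b, cn, plates, rng,
                         marker_map=None):
    """Raw A/B channels from copy number and B-allele dosage.

    Expected total signal is ``s_j * c / 2`` with ``s_j`` the per-marker
    brightness; the B channel carries a fraction b/c of it (zero copies
    emit only the background).  Each channel is multiplied by log-normal
    intensity noise and a per (marker, plate) batch effect, and the A
    channel additionally by the per-marker dye imbalance the psi
    correction is meant to undo.
    """
    n, m = cn.shape
    if np.any(b > cn):
        raise ValueError("B-allele dosage cannot exceed copy number")
    s = 2.0 * np.exp(rng.normal(0.0, config.brightness_sd, size=m))
    gamma = np.exp(rng.normal(0.0, config.channel_imbalance_sd, size=m))
    plate_codes, plate_idx = np.unique(plates, return_inverse=True)
    plate_eff = np.exp(rng.normal(0.0, config.sigma_plate,
                                  size=(len(plate_codes), m)))
    pe = plate_eff[plate_idx]  # (n, m)
    with np.errstate(invalid="ignore"):
        b_share = np.where(cn > 0, b / np.maximum(cn, 1), 0.0)
    mu = s[None, :] * cn / 2.0
    noise_a = np.exp(rng.normal(0.0, config.sigma, size=(n, m)))
    noise_b = np.exp(rng.normal(0.0, config.sigma, size=(n, m)))
    A = mu * (1.0 - b_share) * noise_a * pe
    B = mu * b_share * noise_b * pe
    A = gamma[None, :] * A
    zero = cn == 0
    if zero.any():
        A[zero] = config.background * noise_a[zero]
        B[zero] = config.background * noise_b[zero]
    return A, B


def simulate_survival(config: SimulationConfig, log_risk, rng,
                      max_redraw_rounds: int = 1000):
    """Exponential PH survival with delayed entry and admin censoring.

    ``T ~ Exponential(lambda0 * exp(log_risk))``, entry ``E ~ Uniform(0,
    e_max)``; subject pairs with ``T <= E`` are redrawn until the subject
    would have been alive at enrollment (rejection sampling of the
    enrolled-cases law).  event = 1 if T <= censor time, else exit is the
    censoring time.
    """
    n = log_risk.shape[0]
    lam = config.baseline_hazard * np.exp(log_risk)
    T = rng.exponential(1.0 / lam)
    E = rng.uniform(0.0, config.entry_max_days, size=n) \
        if config.entry_max_days > 0 else np.zeros(n)
    redraws = 0
    need = T <= E
    rounds = 0
    while need.any():
        rounds += 1
        if rounds > max_redraw_rounds:
            raise RuntimeError(
                "left-truncation acceptance rate too low; lower entry_max_days "
                "or the baseline hazard")
        k = int(need.sum())
        redraws += k
        T[need] = rng.exponential(1.0 / lam[need])
        if config.entry_max_days > 0:
            E[need] = rng.uniform(0.0, config.entry_max_days, size=k)
        need = T <= E
        if redraws > 100 * n:
            accept = 1.0 - redraws / (redraws + n)
            if accept < 0.01:
                raise RuntimeError(
                    f"left-truncation acceptance rate {accept:.3%} < 1%; "
                    "adjust entry_max_days or baseline_hazard")
    event = (T <= config.censor_days).astype(int)
    exit_ = np.minimum(T, config.censor_days)
    return E, exit_, event, redraws


def simulate_dataset(config: SimulationConfig):
    """Full synthetic cohort: (marker_map, manifest, panel, truth)."""
    rng = np.random.default_rng(config.seed)
    marker_map = simulate_marker_map(config, rng)
    carrier, cn = simulate_copy_states(config, marker_map, rng)
    gt, b, _ = simulate_genotypes(config, marker_map, cn, rng)

    n = config.n_samples
    sample_ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    plates = np.array([f"P{i % config.n_plates:02d}" for i in range(n)],
                      dtype=object)
    rng.shuffle(plates)
    site = rng.choice(list(config.sites), size=n, p=list(config.site_props))
    age = np.clip(rng.normal(59.4, 11.0, size=n), 22.0, 93.0)
    pcs = rng.normal(0.0, 1.0, size=(n, config.n_pcs))

    site_beta = dict(zip(config.sites, config.beta_site))
    log_hrs = np.array([r.log_hr for r in config.planted_regions])
    log_risk = (config.beta_age * (age - age.mean())
                + np.array([site_beta[s] for s in site])
                + config.beta_pc * pcs[:, 0])
    if carrier.size:
        log_risk = log_risk + carrier @ log_hrs
    entry, exit_, event, redraws = simulate_survival(config, log_risk, rng)

    manifest = SampleManifest(pd.DataFrame({
        "sample_id": sample_ids, "plate_id": plates, "site": site,
        "age_dx": age,
        **{f"pc{k + 1}": pcs[:, k] for k in range(config.n_pcs)},
        "entry_days": entry, "exit_days": exit_, "event": event,
    }))
    A, B = simulate_intensities(config, b, cn, plates, rng)
    panel = IntensityPanel(A=A, B=B, genotype=gt, sample_ids=sample_ids,
                           marker_ids=np.asarray(marker_map.marker_ids,
                                                 dtype=object))
    truth = SyntheticTruth(
        carrier=carrier, regions=tuple(config.planted_regions),
        copy_number=cn, log_hrs=log_hrs, n_truncation_redraws=redraws)
    return marker_map, manifest, panel, truth


def write_dataset(outdir, marker_map, manifest, panel, truth):
    """Write the io-module file set plus a carrier-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker_map.df.to_csv(outdir / "marker_map.tsv", sep="\t", index=False)
    manifest.df.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    gt_str = np.empty(panel.genotype.shape, dtype=object)
    for code, s in ((GT_AA, "AA"), (GT_AB, "AB"), (GT_BB, "BB"),
                    (GT_NC, "NC")):
        gt_str[panel.genotype == code] = s
    for name, mat in (("intensity_a", panel.A), ("intensity_b", panel.B),
                      ("genotype", gt_str)):
        pd.DataFrame(mat, index=pd.Index(panel.sample_ids, name="sample_id"),
                     columns=panel.marker_ids).to_csv(
            outdir / f"{name}.tsv", sep="\t")
    tr = pd.DataFrame(
        truth.carrier.astype(int),
        index=pd.Index(panel.sample_ids, name="sample_id"),
        columns=[f"{r.chrom}:{r.start_marker}+{r.width}:{r.state:+d}"
                 for r in truth.regions])
    tr.to_csv(outdir / "truth.tsv", sep="\t")
    return outdir
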