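"""Readers, writers, and quality-control filters for SNP-array cohorts.

File conventions (all tab-separated with a header row):

* marker map — columns ``marker_id, chrom, pos_bp, probe_class``; chrom is
  an autosome label "1".."22" or "X"; probe_class is ``snp`` or
  ``cnv_only`` (intensity-only probes with no genotype calls).
* intensity matrices — samples in rows (first column ``sample_id``),
  markers in columns; one file per channel (A, B) plus a genotype matrix
  with values AA/AB/BB/NC.
* sample manifest — ``sample_id, plate_id, site, age_dx, pc1..pcK,
  entry_days, exit_days, event``.

Segments are written in the standard SEG format consumed by IGV
(``ID, chrom, loc.start, loc.end, num.mark, seg.mean``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes used throughout
GT_AA, GT_AB, GT_BB, GT_NC = 0, 1, 2, -1
_GT_FROM_STR = {"AA": GT_AA, "AB": GT_AB, "BB": GT_BB, "NC": GT_NC}
_GT_TO_STR = {v: k for k, v in _GT_FROM_STR.items()}

CHROM_ORDER = {str(c): c for c in range(1, 23)}
CHROM_ORDER["X"] = 23

__all__ = [
    "MarkerMap", "SampleManifest", "IntensityPanel", "QCReport",
    "read_marker_map", "read_cohort", "apply_qc",
    "write_seg", "read_seg", "write_results",
    "GT_AA", "GT_AB", "GT_BB", "GT_NC",
]


@dataclass(frozen=True)
class MarkerMap:
    """Validated marker map, sorted by (chrom, pos_bp)."""

    df: pd.DataFrame  # marker_id, chrom, pos_bp, probe_class

    def __post_init__(self):
        df = self.df
        required = ["marker_id", "chrom", "pos_bp", "probe_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        dup = df["marker_id"][df["marker_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate marker_id: {dup.iloc[0]!r}")
        if not pd.api.types.is_integer_dtype(df["pos_bp"]):
            raise ValueError("pos_bp must be integer")
        if (df["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1 (1-based positions)")
        bad = set(df["chrom"].astype(str)) - set(CHROM_ORDER)
        if bad:
            raise ValueError(f"unknown chromosome label(s): {sorted(bad)}")
        bad_pc = set(df["probe_class"]) - {"snp", "cnv_only"}
        if bad_pc:
            raise ValueError(f"unknown probe_class value(s): {sorted(bad_pc)}")
        key = df["chrom"].astype(str).map(CHROM_ORDER)
        df = (df.assign(_k=key)
                .sort_values(["_k", "pos_bp"], kind="stable")
                .drop(columns="_k")
                .reset_index(drop=True))
        object.__setattr__(self, "df", df)

    def __len__(self):
        return len(self.df)

    @property
    def marker_ids(self):
        return self.df["marker_id"].to_numpy()

    @property
    def chrom(self):
        return self.df["chrom"].astype(str).to_numpy()

    @property
    def pos_bp(self):
        return self.df["pos_bp"].to_numpy()

    @property
    def is_snp(self):
        return (self.df["probe_class"] == "snp").to_numpy()

    def chromosomes(self):
        seen = dict.fromkeys(self.chrom)
        return list(seen)


@dataclass(frozen=True)
class SampleManifest:
    """Sample covariates and delayed-entry survival outcome."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        required = ["sample_id", "plate_id", "site", "age_dx",
                    "entry_days", "exit_days", "event"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            d = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id: {d!r}")
        if (df["entry_days"] < 0).any():
            raise ValueError("entry_days must be >= 0")
        if (df["exit_days"] <= df["entry_days"]).any():
            bad = df.loc[df["exit_days"] <= df["entry_days"], "sample_id"].iloc[0]
            raise ValueError(
                f"exit_days must exceed entry_days (sample {bad!r})")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self):
        return len(self.df)

    @property
    def sample_ids(self):
        return self.df["sample_id"].to_numpy()

    @property
    def pc_columns(self):
        return [c for c in self.df.columns if c.startswith("pc")]

    def adjustment_matrix(self, n_pcs: int = 1):
        """Site indicators (reference = first site), age, first n_pcs PCs."""
        df = self.df
        sites = sorted(df["site"].astype(str).unique())
        cols, names = [], []
        for s in sites[1:]:
            cols.append((df["site"].astype(str) == s).astype(float).to_numpy())
            names.append(f"site_{s}")
        cols.append(df["age_dx"].to_numpy(dtype=float))
        names.append("age_dx")
        for c in self.pc_columns[:n_pcs]:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        X = np.column_stack(cols) if cols else np.empty((len(df), 0))
        return X, names

    def survival_data(self, n_pcs: int = 1):
        from .cox import SurvivalData
        X, names = self.adjustment_matrix(n_pcs=n_pcs)
        return SurvivalData(
            entry=self.df["entry_days"].to_numpy(dtype=float),
            exit=self.df["exit_days"].to_numpy(dtype=float),
            event=self.df["event"].to_numpy(dtype=int),
            X=X, names=tuple(names),
        )


@dataclass(frozen=True)
class IntensityPanel:
    """Raw two-channel intensities plus genotype calls, samples x markers."""

    A: np.ndarray
    B: np.ndarray
    genotype: np.ndarray  # int codes GT_*
    sample_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self):
        if not (self.A.shape == self.B.shape == self.genotype.shape):
            raise ValueError("A, B and genotype must share a shape")
        if self.A.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("matrix shape inconsistent with sample/marker ids")
        if (self.A < 0).any() or (self.B < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_samples(self):
        return self.A.shape[0]

    @property
    def n_markers(self):
        return self.A.shape[1]

    def subset(self, sample_mask=None, marker_mask=None) -> "IntensityPanel":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        mm = np.ones(self.n_markers, bool) if marker_mask is None else marker_mask
        return IntensityPanel(
            A=self.A[np.ix_(sm, mm)], B=self.B[np.ix_(sm, mm)],
            genotype=self.genotype[np.ix_(sm, mm)],
            sample_ids=self.sample_ids[sm], marker_ids=self.marker_ids[mm],
        )


@dataclass
class QCReport:
    removed_samples: pd.DataFrame   # sample_id, call_rate
    removed_markers: pd.DataFrame   # marker_id, reason (call_rate | chrX)
    n_samples_in: int
    n_markers_in: int
    n_samples_out: int
    n_markers_out: int

    def __post_init__(self):
        assert self.n_samples_out == self.n_samples_in - len(self.removed_samples)
        assert self.n_markers_out == self.n_markers_in - len(self.removed_markers)

    def to_text(self) -> str:
        lines = [
            f"samples: {self.n_samples_in} in, {len(self.removed_samples)} removed, "
            f"{self.n_samples_out} retained",
            f"markers: {self.n_markers_in} in, {len(self.removed_markers)} removed, "
            f"{self.n_markers_out} retained",
        ]
        for _, r in self.removed_markers.iterrows():
            lines.append(f"marker\t{r['marker_id']}\t{r['reason']}")
        for _, r in self.removed_samples.iterrows():
            lines.append(f"sample\t{r['sample_id']}\tcall_rate={r['call_rate']:.4f}")
        return "\n".join(lines)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str,
                                            "probe_class": str})
    try:
        df["pos_bp"] = pd.to_numeric(df["pos_bp"], downcast=None)
    except (ValueError, KeyError) as e:
        raise ValueError(f"cannot parse pos_bp column: {e}") from e
    if not pd.api.types.is_integer_dtype(df["pos_bp"]):
        raise ValueError("non-integer pos_bp value in marker map")
    return MarkerMap(df)


def _read_matrix(path, kind):
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_cohort(manifest_path, intensity_a_path, intensity_b_path,
                genotype_path, marker_map: MarkerMap):
    """Load manifest + intensity matrices, aligned to the marker map order.

    Every manifest sample must have one row in each matrix and every marker
    of the map one column; extra matrix rows or missing columns raise.
    """
    manifest = SampleManifest(pd.read_csv(
        manifest_path, sep="\t", dtype={"sample_id": str, "plate_id": str}))
    a = _read_matrix(intensity_a_path, "A")
    b = _read_matrix(intensity_b_path, "B")
    g = _read_matrix(genotype_path, "genotype")

    sample_ids = list(manifest.sample_ids)
    for name, df in (("A", a), ("B", b), ("genotype", g)):
        extra = set(df.index) - set(sample_ids)
        if extra:
            raise ValueError(
                f"sample {sorted(extra)[0]!r} present in {name} matrix but "
                "absent from manifest")
        missing = set(sample_ids) - set(df.index)
        if missing:
            raise ValueError(
                f"sample {sorted(missing)[0]!r} in manifest missing from "
                f"{name} matrix")
        missing_m = [m for m in marker_map.marker_ids if m not in df.columns]
        if missing_m:
            raise ValueError(
                f"marker {missing_m[0]!r} missing from {name} matrix")

    cols = list(marker_map.marker_ids)
    a = a.loc[sample_ids, cols]
    b = b.loc[sample_ids, cols]
    g = g.loc[sample_ids, cols]
    gt = g.apply(lambda col: col.map(_GT_FROM_STR)).to_numpy()
    if np.isnan(gt.astype(float)).any():
        raise ValueError("genotype matrix contains values other than AA/AB/BB/NC")
    panel = IntensityPanel(
        A=a.to_numpy(dtype=float), B=b.to_numpy(dtype=float),
        genotype=gt.astype(np.int8),
        sample_ids=np.asarray(sample_ids, dtype=object),
        marker_ids=np.asarray(cols, dtype=object),
    )
    return manifest, panel


def apply_qc(panel: IntensityPanel, marker_map: MarkerMap,
             manifest: SampleManifest, sample_call_rate_min: float = 0.95,
             marker_call_rate_min: float = 0.80, drop_chrX: bool = True):
    """Call-rate and chromosome-X filters.

    Removal uses strict inequality (a rate exactly at the threshold is
    retained).  Call rates are computed over SNP probes only; marker QC is
    applied first and sample call rates are computed over the surviving SNP
    markers.  Returns new (panel, marker_map, manifest) plus a QCReport.
    """
    is_snp = marker_map.is_snp
    called = panel.genotype != GT_NC

    # marker QC: call rate over all samples, chrX removal
    with np.errstate(invalid="ignore"):
        marker_rate = called.mean(axis=0)
    low = is_snp & (marker_rate < marker_call_rate_min)
    chrx = np.zeros(len(marker_map), bool)
    if drop_chrX:
        chrx = marker_map.chrom == "X"
    removed_marker_mask = low | chrx
    reasons = np.where(chrx, "chrX", "call_rate")
    removed_markers = pd.DataFrame({
        "marker_id": marker_map.marker_ids[removed_marker_mask],
        "reason": reasons[removed_marker_mask],
    })
    keep_m = ~removed_marker_mask

    # sample QC on surviving SNP probes
    snp_kept = is_snp & keep_m
    if snp_kept.sum() > 0:
        sample_rate = called[:, snp_kept].mean(axis=1)
    else:
        sample_rate = np.ones(panel.n_samples)
    low_s = sample_rate < sample_call_rate_min
    removed_samples = pd.DataFrame({
        "sample_id": panel.sample_ids[low_s],
        "call_rate": sample_rate[low_s],
    })
    keep_s = ~low_s
    if not keep_s.any():
        raise ValueError("empty cohort: all samples removed by QC")

    new_panel = panel.subset(keep_s, keep_m)
    new_map = MarkerMap(marker_map.df.loc[keep_m].reset_index(drop=True))
    new_manifest = SampleManifest(
        manifest.df.loc[manifest.df["sample_id"].isin(new_panel.sample_ids)]
        .reset_index(drop=True))
    report = QCReport(
        removed_samples=removed_samples, removed_markers=removed_markers,
        n_samples_in=panel.n_samples, n_markers_in=panel.n_markers,
        n_samples_out=new_panel.n_samples, n_markers_out=new_panel.n_markers,
    )
    return new_panel, new_map, new_manifest, report


SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_seg(segments, path):
    """Write segments in SEG format (IGV-compatible).

    ``segments`` is an iterable of objects with attributes
    sample_id, chrom, start_bp, end_bp, n_markers, seg_mean.
    """
    rows = []
    for s in segments:
        if s.end_bp < s.start_bp:
            raise ValueError(
                f"segment end < start ({s.sample_id} {s.chrom}:"
                f"{s.start_bp}-{s.end_bp})")
        rows.append((s.sample_id, s.chrom, int(s.start_bp), int(s.end_bp),
                     int(s.n_markers), float(s.seg_mean)))
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    return df


def write_results(results, path):
    """Write region association results as a TSV (one row per tested unit).

    Columns: region, chrom, start_bp, end_bp, n_gain, n_normal, n_loss,
    hr, ci95_lo, ci95_hi, p, p_2df, p_bonferroni, testable.
    """
    cols = ["region", "chrom", "start_bp", "end_bp", "n_gain", "n_normal",
            "n_loss", "hr", "ci95_lo", "ci95_hi", "p", "p_2df",
            "p_bonferroni", "testable"]
    rows = []
    for r in results:
        rows.append({
            "region": r.label, "chrom": r.chrom, "start_bp": r.start_bp,
            "end_bp": r.end_bp, "n_gain": r.n_gain, "n_normal": r.n_normal,
            "n_loss": r.n_loss, "hr": r.hr, "ci95_lo": r.ci95[0],
            "ci95_hi": r.ci95[1], "p": r.p, "p_2df": r.p_2df,
            "p_bonferroni": r.p_bonferroni, "testable": r.testable,
        })
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
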