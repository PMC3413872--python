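"""Genome-wide CNV burden and its survival association (approach 3).

Burden is the per-sample count of called gain segments, loss segments,
and their total.  Segment sizes are deliberately ignored — a called
aberration counts once however many markers it spans, because breakpoint
(and hence size) estimation from array data is unreliable.  A
marker-weighted variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import NonIdentifiableError, SurvivalData, fit_cox_left_truncated

__all__ = ["BurdenSummary", "compute_burden", "test_burden"]

MEASURES = ("n_losses", "n_gains", "n_total")


@dataclass
class BurdenSummary:
    """Per-sample burden counts, indexed like the calls mapping."""

    df: pd.DataFrame  # sample_id index; n_gains, n_losses, n_total

    def __post_init__(self):
        assert (self.df["n_total"]
                == self.df["n_gains"] + self.df["n_losses"]).all()


def compute_burden(calls_by_sample, weighted: bool = False) -> BurdenSummary:
    """Count called gain and loss segments per sample.

    ``calls_by_sample`` maps sample_id -> list of CopyStateCall.  With
    ``weighted=True`` each aberration contributes its marker count instead
    of 1.
    """
    rows = {}
    for sid, calls in calls_by_sample.items():
        g = l = 0
        for c in calls:
            w = c.segment.n_markers if weighted else 1
            if c.state == 1:
                g += w
            elif c.state == -1:
                l += w
        rows[sid] = (g, l, g + l)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["n_gains", "n_losses", "n_total"])
    df.index.name = "sample_id"
    return BurdenSummary(df=df)


def test_burden(burden: BurdenSummary, survival: SurvivalData):
    """Adjusted left-truncated Cox fit per burden measure.

    Returns (fits, table): ``fits`` maps measure -> CoxFit (or None when
    the measure is constant, flagged untestable in the table); ``table``
    is shaped like a burden summary table — mean (SD) by vital status,
    HR, 95% CI, p.
    """
    fits = {}
    rows = []
    alive = survival.event == 0
    for measure in MEASURES:
        v = burden.df[measure].to_numpy(dtype=float)
        row = {
            "measure": measure,
            "mean_alive": v[alive].mean() if alive.any() else np.nan,
            "sd_alive": v[alive].std(ddof=1) if alive.sum() > 1 else np.nan,
            "mean_deceased": v[~alive].mean() if (~alive).any() else np.nan,
            "sd_deceased": v[~alive].std(ddof=1) if (~alive).sum() > 1 else np.nan,
        }
        try:
            fit = fit_cox_left_truncated(
                survival.with_tested(v, measure))
        except NonIdentifiableError:
            fits[measure] = None
            row.update(hr=np.nan, ci95_lo=np.nan, ci95_hi=np.nan,
                       p=np.nan, testable=False)
            rows.append(row)
            continue
        fits[measure] = fit
        row.update(hr=float(fit.hr[0]), ci95_lo=float(fit.ci95[0, 0]),
                   ci95_hi=float(fit.ci95[0, 1]),
                   p=float(fit.p_wald[0]), testable=True)
        rows.append(row)
    return fits, pd.DataFrame(rows).set_index("measure")
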