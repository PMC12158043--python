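"""Inter-rater agreement statistics: ICC(2,1) and pairwise Pearson r.

The validation statistic is the intraclass correlation coefficient in its
two-way random-effects, absolute-agreement, single-measures form —
ICC(2,1) in the Shrout–Fleiss / McGraw–Wong taxonomy.  With n stimuli
(rows) and k raters (columns), a two-way ANOVA decomposes the table into
row, column and residual mean squares (MSR, MSC, MSE) and

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

The 95% confidence interval is the exact F-based interval of McGraw & Wong
(1996), the same formulas SPSS implements.  Interpretation bands follow
Koo & Li (2016): > 0.9 excellent, 0.75–0.9 good, 0.5–0.75 moderate,
< 0.5 poor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_model import FixationScore, RaterTable

__all__ = ["ICCResult", "icc_2_1", "pearson_pairwise", "build_rater_table", "icc_band"]

log = logging.getLogger(__name__)

AUTO_RATER_ID = "auto"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    band: Literal["excellent", "good", "moderate", "poor"]

    def __post_init__(self):
        if not (self.ci_low <= self.icc + 1e-12 and self.icc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the estimate")


def icc_band(icc: float) -> str:
    """Koo–Li interpretation: >0.9 excellent, [0.75,0.9] good, [0.5,0.75) moderate, <0.5 poor."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def icc_2_1(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its exact F-based confidence interval.

    Rows with any missing cell are dropped (listwise).  Requires at least
    2 complete rows, 2 raters, and nonzero total variance.
    """
    data = table.complete_rows()
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete rows and >= 2 raters, got n={n}, k={k}")
    if np.ptp(data) == 0:
        raise ValueError("ICC undefined: zero variance in table")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    mse = max(mse, 0.0)  # guard tiny negative rounding

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom

    ci_low, ci_high = _icc21_ci(msr, msc, mse, n, k, alpha)
    # numeric guard: the exact interval can round past the point estimate
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n=n,
        k=k,
        band=icc_band(float(icc)),
    )


def _icc21_ci(
    msr: float, msc: float, mse: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    """McGraw–Wong exact CI for ICC(A,1) under the two-way random model."""
    if mse == 0:
        return 1.0, 1.0
    fj = msc / mse
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # Satterthwaite df of the denominator pivot (McGraw & Wong 1996, ICC(A,1))
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_u * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(lower), float(upper)


def pearson_pairwise(
    table: RaterTable, reference_rater: str
) -> dict[str, float]:
    """Pearson r between the reference rater and each other rater.

    Pairs use rows complete for both raters; each pair needs >= 3 such rows
    and nonzero variance in both columns.
    """
    if reference_rater not in table.rater_ids:
        raise ValueError(f"unknown rater {reference_rater!r}")
    ref_j = table.rater_ids.index(reference_rater)
    out: dict[str, float] = {}
    for j, rid in enumerate(table.rater_ids):
        if j == ref_j:
            continue
        x, y = table.values[:, ref_j], table.values[:, j]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"pair ({reference_rater}, {rid}): fewer than 3 complete rows")
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise ValueError(f"pair ({reference_rater}, {rid}): zero variance")
        out[rid] = float(stats.pearsonr(xs, ys).statistic)
    return out


def build_rater_table(
    auto: Sequence[FixationScore],
    manual: pd.DataFrame,
    metric: Literal["TOFF", "TFD"],
) -> RaterTable:
    """Assemble the stimuli x raters matrix for one metric.

    The automatic scorer occupies the first column (rater id ``auto``);
    each manual rater from the annotation table gets a column.  Cells are
    NaN where a value is missing (QC-rejected stimulus, absent TOFF,
    missing annotation); agreement statistics later drop such rows
    listwise.  Raises if no stimulus appears in both sources.
    """
    col = "toff" if metric == "TOFF" else "tfd"
    auto_vals: dict[str, float] = {}
    for s in auto:
        if s.qc != "accepted":
            auto_vals[s.stimulus_id] = float("nan")
        else:
            auto_vals[s.stimulus_id] = s.toff if metric == "TOFF" else s.tfd

    manual = manual.copy()
    manual["stimulus_id"] = manual["stimulus_id"].astype(str)
    rater_ids = sorted(manual["rater_id"].astype(str).unique())
    pivot = manual.pivot_table(
        index="stimulus_id", columns="rater_id", values=col, aggfunc="first"
    )

    stim_ids = [sid for sid in auto_vals if sid in pivot.index]
    if not stim_ids:
        raise ValueError("no overlapping stimuli between automatic and manual tables")

    cols = [AUTO_RATER_ID] + rater_ids
    values = np.full((len(stim_ids), len(cols)), np.nan)
    for i, sid in enumerate(stim_ids):
        values[i, 0] = auto_vals[sid]
        for j, rid in enumerate(rater_ids, start=1):
            if rid in pivot.columns:
                values[i, j] = pivot.loc[sid, rid]

    table = RaterTable(metric=metric, values=values, rater_ids=cols, stimulus_ids=stim_ids)
    dropped = len(stim_ids) - table.n_complete
    if dropped:
        log.info("%s table: %d of %d stimuli dropped (missing cells)", metric, dropped, len(stim_ids))
    return table
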