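"""Evaluation statistics: precision (CV), linearity (R^2 with a
small-sample significance threshold), accuracy (%Acc), fold change, and
delta-score site localization.

Precision is the coefficient of variation of replicate measurements,
100 * sd / mean.  Linearity regresses a peptide's normalized intensity on
the mixing proportion of the stimulated extract and reports the squared
Pearson correlation; significance uses the exact two-sided critical value
of r for the number of points used (r* = t / sqrt(t^2 + n - 2), t the
0.975 Student quantile on n-2 df; for n = 5 this is 0.878).  Accuracy is
the percentage deviation of each observed point from the fitted line,
|fitted - observed| / observed * 100, averaged over retained points;
observations below a floor (default 1% of the row maximum, e.g. the 0%
dilution point of a fully responsive peptide) are excluded from the mean
and counted, because the formula degenerates as the observed value
approaches zero.

Note on the significance threshold: the conventional cutoff "R^2 > 0.878
for five points" quotes the critical value of r, not of R^2 (the critical
R^2 at n = 5 would be 0.878^2 ~ 0.771).  The implementation applies the
threshold to |r| and reports both r and R^2 so the discrepancy is visible
rather than silently inherited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ms_io import DesignTable, IntensityMatrix

#: CV histogram bin edges (percent): 0-10, 10-20, ..., 90-100, >=100
CV_BINS = tuple(float(x) for x in range(0, 101, 10)) + (np.inf,)


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample sd (n-1) / mean.

    NA when fewer than two non-missing values or a non-positive mean.
    """
    v = np.asarray(pd.Series(values).dropna(), float)
    if v.size < 2:
        return np.nan
    m = v.mean()
    if m <= 0:
        return np.nan
    return float(100.0 * v.std(ddof=1) / m)


@dataclass
class PrecisionSummary:
    per_peptide_cv: pd.Series  # percent, NaN where undefined
    mean_cv: float
    histogram: pd.Series  # counts per CV bin
    readout: str
    n_peptides: int  # peptides with a defined CV


def precision_summary(matrix: IntensityMatrix,
                      design: DesignTable | None = None,
                      group: str | None = None) -> PrecisionSummary:
    """Per-peptide CV across replicate columns plus the binned distribution.

    With a design table, restricts to the runs of ``group`` (or the single
    group when only one exists); otherwise all columns are treated as one
    replicate group.
    """
    cols = list(matrix.values.columns)
    if design is not None:
        groups = design.groups()
        if group is None:
            if len(groups) != 1:
                raise ValueError(f"specify one of the groups {sorted(groups)}")
            group = next(iter(groups))
        cols = [c for c in groups[group] if c in matrix.values.columns]
    per_cv = matrix.values[cols].apply(cv, axis=1)
    defined = per_cv.dropna()
    hist = pd.cut(defined, bins=list(CV_BINS), right=False,
                  include_lowest=True).value_counts().sort_index()
    return PrecisionSummary(per_cv, float(defined.mean()) if len(defined) else np.nan,
                            hist, matrix.readout, int(len(defined)))


def critical_r(n_points: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson correlation at significance ``alpha``.

    r* = t / sqrt(t^2 + n - 2) with t the (1 - alpha/2) Student quantile on
    n - 2 degrees of freedom.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points for a correlation test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, n_points - 2)
    return float(t / np.sqrt(t * t + n_points - 2))


@dataclass
class LinearityResult:
    peptide_id: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    n_points: int
    critical_r: float
    significant: bool
    log2_fold: float  # log2(fitted at max proportion / fitted at min)


def linearity(row, proportions, alpha: float = 0.05,
              peptide_id: str = "") -> LinearityResult:
    """Ordinary least squares of intensity on mixing proportion for one
    peptide; missing points are dropped pairwise."""
    y = np.asarray(row, float)
    x = np.asarray(proportions, float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return LinearityResult(peptide_id, np.nan, np.nan, np.nan, np.nan,
                               n, np.nan, False, np.nan)
    if np.std(y) == 0 or np.std(x) == 0:
        return LinearityResult(peptide_id, np.nan, np.nan, np.nan, np.nan,
                               n, critical_r(n, alpha), False, np.nan)
    fit = stats.linregress(x, y)
    rc = critical_r(n, alpha)
    lo, hi = fit.intercept + fit.slope * x.min(), fit.intercept + fit.slope * x.max()
    fold = float(np.log2(hi / lo)) if lo > 0 and hi > 0 else np.nan
    return LinearityResult(peptide_id, float(fit.slope), float(fit.intercept),
                           float(fit.rvalue), float(fit.rvalue ** 2), n, rc,
                           bool(abs(fit.rvalue) > rc), fold)


def linearity_table(matrix: IntensityMatrix, design: DesignTable,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-peptide linearity over the design's mixing proportions."""
    prop = design.proportions()
    cols = [c for c in matrix.values.columns if c in prop.index]
    if len(cols) < 3:
        raise ValueError("need at least 3 runs with mixing proportions")
    x = prop[cols].to_numpy(float)
    rows = [linearity(matrix.values.loc[pid, cols], x, alpha, pid)
            for pid in matrix.values.index]
    return pd.DataFrame([vars(r) for r in rows]).set_index("peptide_id")


@dataclass
class AccuracyResult:
    peptide_id: str
    points: pd.DataFrame  # proportion, observed, theoretical, pct_dev, retained
    mean_pct_acc: float  # over retained points
    n_excluded: int


def accuracy(row, proportions, fit: LinearityResult,
             floor_frac: float = 0.01, peptide_id: str = "") -> AccuracyResult:
    """Percentage deviation of each dilution point from the fitted line.

    %dev = |theoretical - observed| / observed * 100, theoretical being the
    fitted value at that proportion.  Points with observed below
    ``floor_frac`` of the row maximum are excluded from the mean (the
    formula blows up near zero) and reported.
    """
    y = np.asarray(row, float)
    x = np.asarray(proportions, float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    theo = fit.intercept + fit.slope * x
    floor = floor_frac * y.max() if y.size else np.nan
    retained = y > floor
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(theo - y) / y * 100.0
    pts = pd.DataFrame({"proportion": x, "observed": y, "theoretical": theo,
                        "pct_dev": dev, "retained": retained})
    mean = float(dev[retained].mean()) if retained.any() else np.nan
    return AccuracyResult(peptide_id, pts, mean, int((~retained).sum()))


def accuracy_table(matrix: IntensityMatrix, design: DesignTable,
                   fits: pd.DataFrame | None = None,
                   floor_frac: float = 0.01,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-peptide mean %Acc over the mixing series.

    ``fits`` is the output of :func:`linearity_table` (recomputed when
    omitted).  The returned table carries mean_pct_acc and the number of
    floored points per peptide.
    """
    if fits is None:
        fits = linearity_table(matrix, design, alpha)
    prop = design.proportions()
    cols = [c for c in matrix.values.columns if c in prop.index]
    x = prop[cols].to_numpy(float)
    rows = []
    for pid in matrix.values.index:
        f = fits.loc[pid]
        if np.isnan(f["slope"]):
            rows.append({"peptide_id": pid, "mean_pct_acc": np.nan,
                         "n_excluded": 0})
            continue
        fit = LinearityResult(pid, f["slope"], f["intercept"], f["r"],
                              f["r_squared"], int(f["n_points"]),
                              f["critical_r"], bool(f["significant"]),
                              f["log2_fold"])
        res = accuracy(matrix.values.loc[pid, cols], x, fit, floor_frac, pid)
        rows.append({"peptide_id": pid, "mean_pct_acc": res.mean_pct_acc,
                     "n_excluded": res.n_excluded})
    return pd.DataFrame(rows).set_index("peptide_id")


def localize_site(score_first: float, score_second: float,
                  delta_threshold: float) -> str:
    """Delta-score site localization: 'localized' when the margin between
    the best and second-best site assignment reaches the threshold, else
    'ambiguous'.  The threshold is a required analyst choice."""
    if score_second > score_first:
        raise ValueError("score_first must be >= score_second")
    if delta_threshold <= 0:
        raise ValueError("delta_threshold must be positive")
    return "localized" if (score_first - score_second) >= delta_threshold \
        else "ambiguous"
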