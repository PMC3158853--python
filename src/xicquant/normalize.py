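"""Two-step normalization and replicate-outlier handling.

Raw XIC intensities carry run-to-run global factors (injection amount,
spray efficiency).  Step one divides each run's column by that run's total
MS1 chromatogram intensity — an identification-independent denominator —
and rescales by the mean of the totals so magnitudes stay interpretable.
Step two expresses each peptide row as a percentage of its largest value
across samples, which puts all peptides on a common 0-100 scale for the
dilution-series statistics.

A replicate whose disagreement with the others is not a global factor
cannot be repaired by normalization; it is detected (median absolute log2
ratio to the other replicates' median profile above a threshold) and
flagged.  Removal is a separate, explicit call: the analyst confirms the
flag, mirroring the normalize-first-then-remove order of a replicate QC
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ms_io import FormatError, IntensityMatrix, MsRun


@dataclass
class NormalizationReport:
    totals: pd.Series  # per run: total MS1 intensity
    scale_factors: pd.Series  # per run: divisor applied (total / mean_total)
    row_max: pd.Series | None = None  # per peptide, set by percent_of_max


@dataclass
class OutlierReport:
    """Per replicate run, the median over peptides of |log2(cell /
    median-of-other-replicates)|, and the flag."""

    deviation: pd.Series
    flagged: pd.Series
    threshold_log2: float

    @property
    def flagged_runs(self) -> list[str]:
        return list(self.flagged[self.flagged].index)


def _totals_from(runs: Sequence[MsRun] | Mapping[str, float],
                 columns: Sequence[str]) -> pd.Series:
    if isinstance(runs, Mapping):
        totals = pd.Series({k: float(v) for k, v in runs.items()})
    else:
        totals = pd.Series({r.run_id: r.total_ms1_intensity for r in runs})
    missing = [c for c in columns if c not in totals.index]
    if missing:
        raise FormatError(f"no run / total intensity for columns: {missing}")
    return totals[list(columns)]


def normalize_total(matrix: IntensityMatrix,
                    runs: Sequence[MsRun] | Mapping[str, float],
                    denominator: str = "tic") -> tuple[IntensityMatrix,
                                                       NormalizationReport]:
    """Divide each column by its run's total intensity, rescaled by the
    mean of the totals.

    ``denominator="tic"`` (default) uses the total MS1 chromatogram
    intensity of the run; ``"quantified-sum"`` uses the column sum of the
    quantified peptides instead.
    """
    if matrix.state != "raw":
        raise FormatError(f"matrix already normalized (state {matrix.state})")
    if denominator == "tic":
        totals = _totals_from(runs, matrix.values.columns)
    elif denominator == "quantified-sum":
        totals = matrix.values.sum(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if (totals <= 0).any():
        bad = list(totals[totals <= 0].index)
        raise FormatError(f"non-positive total intensity for runs: {bad}")
    factors = totals / totals.mean()
    out = matrix.advanced(matrix.values / factors, "total_normalized")
    out.params["norm_denominator"] = denominator
    return out, NormalizationReport(totals, factors)


def percent_of_max(matrix: IntensityMatrix) -> tuple[IntensityMatrix,
                                                     NormalizationReport]:
    """Scale each row so its maximum non-missing value is 100.  All-missing
    rows stay all-missing."""
    if matrix.state != "total_normalized":
        raise FormatError(
            f"percent_of_max expects a total-normalized matrix, got {matrix.state}")
    row_max = matrix.values.max(axis=1, skipna=True)
    scaled = matrix.values.div(row_max, axis=0) * 100.0
    out = matrix.advanced(scaled, "percent_of_max")
    return out, NormalizationReport(pd.Series(dtype=float),
                                    pd.Series(dtype=float), row_max)


def detect_outliers(matrix: IntensityMatrix,
                    run_ids: Sequence[str] | None = None,
                    threshold_log2: float = 1.0) -> OutlierReport:
    """Flag replicates that deviate from the consensus profile.

    For each replicate r, compute per peptide log2(x_pr / median of the
    peptide over the *other* replicates), and flag r when the median of
    the absolute ratios exceeds ``threshold_log2``.  Needs >= 3 replicates
    (with two, the outlier is undecidable).
    """
    cols = list(run_ids) if run_ids is not None else list(matrix.values.columns)
    if len(cols) < 3:
        raise FormatError("outlier detection needs at least 3 replicates")
    sub = matrix.values[cols]
    dev = {}
    for c in cols:
        others = sub.drop(columns=c).median(axis=1, skipna=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(sub[c] / others)
        ratio = ratio.replace([np.inf, -np.inf], np.nan).dropna()
        dev[c] = float(ratio.abs().median()) if len(ratio) else np.nan
    deviation = pd.Series(dev)
    flagged = deviation > threshold_log2
    return OutlierReport(deviation, flagged, threshold_log2)


def remove_runs(matrix: IntensityMatrix,
                run_ids: Sequence[str]) -> IntensityMatrix:
    """Explicitly drop (outlier) runs from the matrix."""
    missing = [r for r in run_ids if r not in matrix.values.columns]
    if missing:
        raise FormatError(f"runs not in matrix: {missing}")
    return matrix.dropped(run_ids)
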