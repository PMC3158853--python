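"""Targeted XIC construction and chromatographic peak quantification.

The method is identification-driven ("match between runs" avant la lettre):
every peptide ion in the database is quantified in every run, whether or
not it was fragmented and identified there — the remedy for the stochastic
undersampling of data-dependent acquisition.  A quantification is accepted
only when it survives three gates:

* m/z: for each of the first three isotopes, centroids within a closed
  ppm window (default 7 ppm) around that isotope's own theoretical m/z;
* retention time: scans within a window (default +/- 5 min) around the
  database reference tR;
* isotope distribution: Pearson correlation between observed apex-scan
  isotope intensities and the theoretical envelope above a threshold
  (default 0.95).

The reported peptide intensity is by default the apex height / area of the
summed three-isotope trace (robust to single-trace noise); a mono-only mode
reads the monoisotopic trace alone.  Absence of signal is always NA, never
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import IsotopeEnvelope
from .ms_io import IntensityMatrix, MsRun, PeptideRecord


@dataclass(frozen=True)
class QuantParams:
    ppm: float = 7.0
    tR_window: float = 5.0  # minutes, half-width
    iso_corr_threshold: float = 0.95
    n_isotopes: int = 3
    mono_only: bool = False  # report the monoisotopic trace instead of the sum
    peak_floor_frac: float = 0.05  # integration stops below this fraction of apex


@dataclass
class Xic:
    """Per-isotope intensity traces on the shared scan grid of the tR
    window.  A zero means no centroid fell inside the m/z window."""

    times: np.ndarray  # minutes, ascending
    intensities: np.ndarray  # (n_isotopes, n_scans)
    target_mz: np.ndarray
    ppm: float

    def summed(self) -> np.ndarray:
        return self.intensities.sum(axis=0)


@dataclass
class ChromPeak:
    apex_time: float  # minutes
    apex_height: float  # counts
    area: float  # counts * seconds (trapezoid between bounds)
    left_bound: float  # minutes
    right_bound: float
    n_points: int
    apex_index: int  # index into the Xic grid


@dataclass
class QuantResult:
    peptide_id: str
    run_id: str
    peak: ChromPeak | None
    iso_correlation: float | None
    accepted: bool
    rejection_reason: str | None  # no_signal | low_iso_correlation | out_of_tR_window


class _RunIndex:
    """All centroids of a run flattened and sorted by m/z, so each isotope
    trace is one binary search plus a grouped max."""

    def __init__(self, run: MsRun):
        self.times = run.scan_times
        mz_parts, int_parts, scan_parts = [], [], []
        for i, scan in enumerate(run.scans):
            if scan.mz_array.size:
                mz_parts.append(scan.mz_array)
                int_parts.append(scan.intensity_array)
                scan_parts.append(np.full(scan.mz_array.size, i, dtype=np.int64))
        if mz_parts:
            mz = np.concatenate(mz_parts)
            order = np.argsort(mz, kind="stable")
            self.mz = mz[order]
            self.intensity = np.concatenate(int_parts)[order]
            self.scan_idx = np.concatenate(scan_parts)[order]
        else:
            self.mz = np.array([])
            self.intensity = np.array([])
            self.scan_idx = np.array([], dtype=np.int64)


def _get_index(run: MsRun) -> _RunIndex:
    idx = getattr(run, "_xic_index", None)
    if idx is None:
        idx = _RunIndex(run)
        run._xic_index = idx  # cached; MsRun scans are treated as immutable
    return idx


def build_xic(run: MsRun, envelope: IsotopeEnvelope, reference_tR: float,
              ppm: float = 7.0, tR_window: float = 5.0) -> Xic | None:
    """Extract per-isotope traces around ``reference_tR``.

    For each scan in the window and each isotope, the trace value is the
    maximum centroid intensity within the closed ppm window around that
    isotope's m/z (0 if none).  Returns None when no scan falls in the tR
    window.
    """
    idx = _get_index(run)
    i0, i1 = np.searchsorted(idx.times, [reference_tR - tR_window,
                                         reference_tR + tR_window])
    if i1 <= i0:
        return None
    n = i1 - i0
    traces = np.zeros((len(envelope.mz_values), n))
    for k, m in enumerate(envelope.mz_values):
        tol = m * ppm * 1e-6
        lo = np.searchsorted(idx.mz, m - tol, side="left")
        hi = np.searchsorted(idx.mz, m + tol, side="right")
        if hi <= lo:
            continue
        scans = idx.scan_idx[lo:hi]
        sel = (scans >= i0) & (scans < i1)
        np.maximum.at(traces[k], scans[sel] - i0, idx.intensity[lo:hi][sel])
    return Xic(idx.times[i0:i1], traces, np.asarray(envelope.mz_values), ppm)


def detect_peak(xic: Xic, floor_frac: float = 0.05) -> ChromPeak | None:
    """Pick the apex of the summed trace and integrate between bounds.

    The apex is the scan maximising the summed three-isotope intensity; the
    bounds extend outward to the first scan below ``floor_frac`` of the
    apex or to a local minimum, whichever comes first.  Area is the
    trapezoidal integral of the summed trace between the bounds, in
    counts*seconds.  Returns None on an all-zero trace.
    """
    summed = xic.summed()
    if summed.size == 0 or summed.max() <= 0:
        return None
    apex = int(np.argmax(summed))
    floor = floor_frac * summed[apex]
    left = apex
    while left > 0:
        if summed[left - 1] < floor:
            left -= 1  # include the sub-floor scan as the bound
            break
        if summed[left - 1] > summed[left]:
            break  # local minimum at `left`
        left -= 1
    right = apex
    last = summed.size - 1
    while right < last:
        if summed[right + 1] < floor:
            right += 1
            break
        if summed[right + 1] > summed[right]:
            break
        right += 1
    seg_t = xic.times[left:right + 1] * 60.0  # seconds
    area = float(np.trapezoid(summed[left:right + 1], seg_t)) if right > left else 0.0
    return ChromPeak(
        apex_time=float(xic.times[apex]),
        apex_height=float(summed[apex]),
        area=area,
        left_bound=float(xic.times[left]),
        right_bound=float(xic.times[right]),
        n_points=right - left + 1,
        apex_index=apex,
    )


def isotope_correlation(xic: Xic, envelope: IsotopeEnvelope,
                        peak: ChromPeak) -> float:
    """Pearson correlation between the observed apex-scan isotope
    intensities and the theoretical relative abundances.  Zero variance in
    either vector yields 0 (which downstream rejects)."""
    obs = xic.intensities[:, peak.apex_index]
    theo = envelope.relative_abundances
    if np.std(obs) == 0 or np.std(theo) == 0:
        return 0.0
    return float(np.corrcoef(obs, theo)[0, 1])


def quantify_one(run: MsRun, record: PeptideRecord,
                 params: QuantParams = QuantParams()) -> QuantResult:
    """Quantify a single peptide ion in a single run."""
    env = record.ion.envelope(params.n_isotopes)
    xic = build_xic(run, env, record.ion.reference_tR,
                    params.ppm, params.tR_window)
    if xic is None:
        return QuantResult(record.peptide_id, run.run_id, None, None,
                           False, "out_of_tR_window")
    peak = detect_peak(xic, params.peak_floor_frac)
    if peak is None:
        return QuantResult(record.peptide_id, run.run_id, None, None,
                           False, "no_signal")
    r = isotope_correlation(xic, env, peak)
    if not r > params.iso_corr_threshold:
        return QuantResult(record.peptide_id, run.run_id, peak, r,
                           False, "low_iso_correlation")
    if params.mono_only:
        mono = xic.intensities[0]
        li = int(np.searchsorted(xic.times, peak.left_bound))
        ri = int(np.searchsorted(xic.times, peak.right_bound))
        area = float(np.trapezoid(mono[li:ri + 1], xic.times[li:ri + 1] * 60.0)) \
            if ri > li else 0.0
        peak = ChromPeak(peak.apex_time, float(mono[peak.apex_index]), area,
                         peak.left_bound, peak.right_bound,
                         peak.n_points, peak.apex_index)
    return QuantResult(record.peptide_id, run.run_id, peak, r, True, None)


def quantify(runs: Sequence[MsRun], peptides: Sequence[PeptideRecord],
             params: QuantParams = QuantParams()
             ) -> tuple[IntensityMatrix, IntensityMatrix, list[QuantResult]]:
    """Quantify every peptide in every run.

    Returns the height matrix, the area matrix (both raw, NA where
    rejected) and the per-pair QC log.
    """
    ids = [p.peptide_id for p in peptides]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate peptide ids: {dup}")
    run_ids = [r.run_id for r in runs]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError("duplicate run ids")
    heights = pd.DataFrame(np.nan, index=ids, columns=run_ids)
    areas = pd.DataFrame(np.nan, index=ids, columns=run_ids)
    results: list[QuantResult] = []
    for run in runs:
        for rec in peptides:
            res = quantify_one(run, rec, params)
            results.append(res)
            if res.accepted:
                heights.loc[rec.peptide_id, run.run_id] = res.peak.apex_height
                areas.loc[rec.peptide_id, run.run_id] = res.peak.area
    meta = {"ppm": params.ppm, "tR_window": params.tR_window,
            "iso_corr_threshold": params.iso_corr_threshold,
            "n_isotopes": params.n_isotopes, "mono_only": params.mono_only}
    return (IntensityMatrix(heights, "height", ("raw",), dict(meta)),
            IntensityMatrix(areas, "area", ("raw",), dict(meta)),
            results)


def results_table(results: Sequence[QuantResult]) -> pd.DataFrame:
    """QC log as a flat table."""
    rows = []
    for r in results:
        rows.append({
            "peptide_id": r.peptide_id,
            "run_id": r.run_id,
            "accepted": r.accepted,
            "rejection_reason": r.rejection_reason or "",
            "iso_correlation": np.nan if r.iso_correlation is None else r.iso_correlation,
            "apex_time": np.nan if r.peak is None else r.peak.apex_time,
            "apex_height": np.nan if r.peak is None else r.peak.apex_height,
            "area": np.nan if r.peak is None else r.peak.area,
            "n_points": 0 if r.peak is None else r.peak.n_points,
        })
    return pd.DataFrame(rows)
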