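"""Synthetic LC-MS1 runs with ground truth.

The generator emulates the acquisition geometry the quantification method
assumes: a data-dependent Orbitrap run whose survey scans recur every
~2.5 s (the duty cycle), chromatographic peaks ~30 s at the base (modelled
as Gaussians with sigma = base/4, reading "base" as +/-2 sigma), and each
peptide contributing its first three theoretical isotopes as co-eluting
centroid traces.  With those defaults every elution peak is covered by at
least 10 survey points, which is the sampling density the extracted-ion-
chromatogram readout needs.

Statistical structure, per peptide-and-run:

* a global per-run scale factor (spray/injection efficiency), log-uniform;
* multiplicative lognormal noise applied to the whole elution profile —
  replicate-to-replicate intensity variability, not shot noise per scan;
* optional retention-time jitter across runs and uniform ppm mass error on
  every centroid;
* optionally one "outlier" replicate whose per-peptide distortions are
  drawn wide and independently, so a single global rescale cannot repair it.

Ground truth records, per peptide and run, the clean (pre-noise) and the
applied (noise-and-scale) apex height, the Gaussian closed-form area
(height * sigma * sqrt(2*pi), in counts*seconds) and the realised retention
time — the oracle against which quantification is checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import MODIFICATIONS, PeptideIon, theoretical_envelope
from .ms_io import (DesignTable, Ms1Scan, MsRun, PeptideRecord,
                    write_design, write_mzml, write_peptide_db)

_AA = "ACDEFGHIKLMNPQRSTVWY"
# residue sampling weights loosely following proteome frequencies
_AA_W = np.array([8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
                  2.4, 4.1, 4.7, 4.0, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9])
_AA_W = _AA_W / _AA_W.sum()


@dataclass(frozen=True)
class OutlierSpec:
    """Distort one replicate: each peptide's profile is multiplied by an
    independent draw from U(lo, hi)."""

    run_index: int = 1
    distortion_range: tuple[float, float] = (0.1, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    n_peptides: int = 200
    charge_range: tuple[int, int] = (2, 3)
    length_range: tuple[int, int] = (8, 22)  # residues
    gradient_length: float = 45.0  # minutes
    scan_interval: float = 2.5  # seconds
    peak_base_width: float = 30.0  # seconds; Gaussian sigma = base/4
    noise_sigma_log: float = 0.04  # sd of ln-scale multiplicative noise
    run_scale_range: tuple[float, float] = (0.7, 1.4)  # log-uniform bounds
    background_fraction: float = 0.0  # extra unphosphorylated, flat peptides
    mz_jitter_ppm: float = 2.0  # uniform +/- ppm per centroid
    tR_jitter_sd: float = 0.3  # minutes, across runs
    intensity_range: tuple[float, float] = (1e3, 1e6)  # log-uniform heights
    mixing_baseline: float = 20.0  # height at 0% for responsive peptides
    mixing_top: float = 100.0  # height at 100%
    # Unmodified, non-responsive peptides added to mixing series so the total
    # chromatogram intensity is design-independent (the mixtures hold total
    # protein constant; only the responsive subset changes).  Fraction of
    # n_peptides.
    mixing_background_fraction: float = 1.0
    centroid_floor: float = 1e-3  # drop centroids below this fraction of amplitude
    rng_seed: int = 0

    def __post_init__(self):
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        if self.peak_base_width / 60.0 >= self.gradient_length:
            raise ValueError("peak width must be smaller than the gradient span")

    @property
    def sigma_seconds(self) -> float:
        return self.peak_base_width / 4.0

    @property
    def scan_times(self) -> np.ndarray:
        """Survey-scan grid in minutes."""
        return np.arange(0.0, self.gradient_length * 60.0, self.scan_interval) / 60.0


def points_per_peak(config: SimulationConfig) -> int:
    """MS1 points falling within one peak's base (tR +/- base/2) on the
    worst-aligned scan grid."""
    return int(np.floor(config.peak_base_width / config.scan_interval)) + 1


@dataclass
class GroundTruth:
    """Per (peptide, run) injected truth; areas in counts*seconds."""

    table: pd.DataFrame  # peptide_id, run_id, height_clean, height_applied,
    #                      height_sampled, area_applied, tR_actual
    responses: pd.DataFrame | None = None  # peptide_id, baseline, slope (mixing)

    def heights(self, which: str = "applied") -> pd.DataFrame:
        return self.table.pivot(index="peptide_id", columns="run_id",
                                values=f"height_{which}")


def make_peptides(config: SimulationConfig,
                  rng: np.random.Generator,
                  phospho: bool = True,
                  n_background: int | None = None) -> list[PeptideRecord]:
    """Random tryptic-like peptide ions with reference retention times
    spread over the usable gradient window.

    Phosphopeptides carry 1-3 Phospho on S/T/Y; with
    ``background_fraction`` > 0 a proportion of unmodified peptides is
    appended (ids prefixed ``bg``) to mimic incompletely removed
    unphosphorylated background.
    """
    n_bg = (int(round(config.n_peptides * config.background_fraction))
            if n_background is None else n_background)
    margin = 3.0 * config.sigma_seconds / 60.0 + 4.0 * config.tR_jitter_sd
    lo, hi = margin, config.gradient_length - margin
    records = []
    for i in range(config.n_peptides + n_bg):
        is_bg = i >= config.n_peptides
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA), size=length - 1, p=_AA_W))
        seq += rng.choice(["K", "R"])
        mods = []
        if phospho and not is_bg:
            sty = [j + 1 for j, r in enumerate(seq) if r in "STY"]
            if not sty:  # force a phosphorylatable residue
                j = int(rng.integers(0, length - 1))
                seq = seq[:j] + rng.choice(list("STY")) + seq[j + 1:]
                sty = [j + 1]
            n_p = min(len(sty), int(rng.integers(1, 4)))
            for pos in sorted(rng.choice(sty, size=n_p, replace=False)):
                mods.append((int(pos), MODIFICATIONS["Phospho"]))
        z = int(rng.integers(config.charge_range[0], config.charge_range[1] + 1))
        tr = float(rng.uniform(lo, hi))
        ion = PeptideIon(seq, tuple(mods), z, tr)
        pid = f"{'bg' if is_bg else 'pep'}{i:04d}"
        records.append(PeptideRecord(pid, ion))
    return records


def _simulate_run(config: SimulationConfig,
                  peptides: Sequence[PeptideRecord],
                  heights: np.ndarray,
                  run_id: str,
                  scale: float,
                  rng: np.random.Generator) -> tuple[MsRun, pd.DataFrame]:
    """Build one run.  ``heights`` are clean summed-trace apex heights; the
    profile applied to the spectra is heights * scale * lognormal noise."""
    times = config.scan_times  # minutes
    sigma_min = config.sigma_seconds / 60.0
    noise = np.exp(rng.normal(0.0, config.noise_sigma_log, size=len(peptides))) \
        if config.noise_sigma_log > 0 else np.ones(len(peptides))
    tr_jit = rng.normal(0.0, config.tR_jitter_sd, size=len(peptides)) \
        if config.tR_jitter_sd > 0 else np.zeros(len(peptides))

    mz_chunks: list[np.ndarray] = []
    int_chunks: list[np.ndarray] = []
    scan_chunks: list[np.ndarray] = []
    truth_rows = []
    for k, rec in enumerate(peptides):
        env = theoretical_envelope(rec.ion.composition, rec.ion.charge, 3)
        h_applied = heights[k] * scale * noise[k]
        tr = rec.ion.reference_tR + tr_jit[k]
        i0, i1 = np.searchsorted(times, [tr - 5 * sigma_min, tr + 5 * sigma_min])
        profile = np.exp(-0.5 * ((times[i0:i1] - tr) / sigma_min) ** 2)
        # height_sampled: the applied Gaussian's maximum on the scan grid —
        # what an error-free readout of these spectra would report
        h_sampled = h_applied * (profile.max() if profile.size else 0.0)
        truth_rows.append((rec.peptide_id, run_id, heights[k], h_applied,
                           h_sampled,
                           h_applied * config.sigma_seconds * np.sqrt(2 * np.pi), tr))
        if h_applied <= 0 or i0 == i1:
            continue
        # per-isotope amplitude so the *summed* trace apex equals h_applied
        amps = h_applied * env.relative_abundances / env.relative_abundances.sum()
        for iso in range(3):
            inten = amps[iso] * profile
            keep = inten > config.centroid_floor * amps.max()
            if not keep.any():
                continue
            n = int(keep.sum())
            mz = np.full(n, env.mz_values[iso])
            if config.mz_jitter_ppm > 0:
                mz = mz * (1.0 + rng.uniform(-config.mz_jitter_ppm,
                                             config.mz_jitter_ppm, n) * 1e-6)
            mz_chunks.append(mz)
            int_chunks.append(inten[keep])
            scan_chunks.append(np.nonzero(keep)[0] + i0)

    scans: list[Ms1Scan] = []
    if mz_chunks:
        all_mz = np.concatenate(mz_chunks)
        all_int = np.concatenate(int_chunks)
        all_scan = np.concatenate(scan_chunks)
    else:
        all_mz = all_int = all_scan = np.array([])
    order = np.lexsort((all_mz, all_scan)) if all_mz.size else np.array([], int)
    all_mz, all_int, all_scan = all_mz[order], all_int[order], all_scan[order]
    bounds = np.searchsorted(all_scan, np.arange(len(times) + 1))
    for s in range(len(times)):
        lo, hi = bounds[s], bounds[s + 1]
        mz, inten = all_mz[lo:hi], all_int[lo:hi]
        if mz.size > 1:  # merge centroids that collide on the m/z axis
            close = np.diff(mz) < 1e-6
            if close.any():
                group = np.concatenate([[0], np.cumsum(~close)])
                mz = np.array([mz[group == g][0] for g in range(group[-1] + 1)])
                inten = np.array([inten[group == g].sum()
                                  for g in range(group[-1] + 1)])
        scans.append(Ms1Scan(times[s], mz, inten))
    truth = pd.DataFrame(truth_rows, columns=["peptide_id", "run_id",
                                              "height_clean", "height_applied",
                                              "height_sampled", "area_applied",
                                              "tR_actual"])
    return MsRun(run_id, scans), truth


def _run_scales(config: SimulationConfig, n: int,
                rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.run_scale_range
    if lo == hi:
        return np.full(n, float(lo))
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_run(config: SimulationConfig,
                 peptides: Sequence[PeptideRecord] | None = None,
                 heights: np.ndarray | None = None,
                 run_id: str = "run1") -> tuple[MsRun, GroundTruth, list[PeptideRecord]]:
    """Single-run convenience wrapper: one run, one scale factor."""
    rng = np.random.default_rng(config.rng_seed)
    if peptides is None:
        peptides = make_peptides(config, rng)
    if heights is None:
        lo, hi = config.intensity_range
        heights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(peptides)))
    scale = _run_scales(config, 1, rng)[0]
    run, truth = _simulate_run(config, peptides, np.asarray(heights, float),
                               run_id, scale, rng)
    return run, GroundTruth(truth), list(peptides)


def simulate_replicates(
    config: SimulationConfig,
    n_replicates: int = 6,
    outlier_spec: OutlierSpec | None = None,
) -> tuple[list[MsRun], GroundTruth, list[PeptideRecord], DesignTable]:
    """Replicate runs sharing true intensities, differing by per-run scale
    and per-cell noise; optionally one distorted outlier replicate."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(config.rng_seed)
    peptides = make_peptides(config, rng)
    lo, hi = config.intensity_range
    heights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(peptides)))
    scales = _run_scales(config, n_replicates, rng)
    runs, truths = [], []
    for r in range(n_replicates):
        h = heights.copy()
        if outlier_spec is not None and r == outlier_spec.run_index:
            d_lo, d_hi = outlier_spec.distortion_range
            h = h * rng.uniform(d_lo, d_hi, size=len(peptides))
        run, truth = _simulate_run(config, peptides, h, f"rep{r + 1}",
                                   scales[r], rng)
        runs.append(run)
        truths.append(truth)
    design = DesignTable(pd.DataFrame(
        {"group": ["replicates"] * n_replicates, "proportion": np.nan},
        index=pd.Index([r.run_id for r in runs], name="run_id")))
    return runs, GroundTruth(pd.concat(truths, ignore_index=True)), \
        list(peptides), design


def simulate_mixing_series(
    config: SimulationConfig,
    proportions: Sequence[float] = (0, 25, 50, 75, 100),
) -> tuple[list[MsRun], GroundTruth, list[PeptideRecord], DesignTable]:
    """One run per mixing proportion p; each responsive peptide's clean apex
    height is baseline + slope * p (slope from mixing_baseline/mixing_top).

    Non-responsive background peptides (``mixing_background_fraction`` of
    n_peptides, flat at their drawn height) dominate the total chromatogram
    intensity, emulating the equal-total-protein mixtures in which only the
    responsive subset tracks the proportion — without them, normalizing to
    the run total would cancel the very trend the design injects."""
    if any(p < 0 or p > 100 for p in proportions):
        raise ValueError("proportions must lie in [0, 100]")
    rng = np.random.default_rng(config.rng_seed)
    n_bg = int(round(config.n_peptides * config.mixing_background_fraction))
    peptides = make_peptides(config, rng, n_background=n_bg)
    responsive = np.array([not p.peptide_id.startswith("bg") for p in peptides])
    slope = (config.mixing_top - config.mixing_baseline) / 100.0
    lo, hi = config.intensity_range
    flat = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(peptides)))
    scales = _run_scales(config, len(proportions), rng)
    runs, truths = [], []
    for j, p in enumerate(proportions):
        h = np.where(responsive, config.mixing_baseline + slope * float(p), flat)
        run, truth = _simulate_run(config, peptides, h, f"mix{int(p):03d}",
                                   scales[j], rng)
        runs.append(run)
        truths.append(truth)
    responses = pd.DataFrame({
        "peptide_id": [p.peptide_id for p in peptides],
        "baseline": np.where(responsive, config.mixing_baseline, flat),
        "slope": np.where(responsive, slope, 0.0),
    })
    design = DesignTable(pd.DataFrame(
        {"group": np.nan, "proportion": [float(p) for p in proportions]},
        index=pd.Index([r.run_id for r in runs], name="run_id")))
    return runs, GroundTruth(pd.concat(truths, ignore_index=True), responses), \
        list(peptides), design


def write_dataset(out_dir: str | Path,
                  runs: Sequence[MsRun],
                  truth: GroundTruth,
                  peptides: Sequence[PeptideRecord],
                  design: DesignTable) -> None:
    """Emit mzML files plus peptide-DB, design and ground-truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run in runs:
        write_mzml(run, out / f"{run.run_id}.mzML")
    write_peptide_db(peptides, out / "peptides.tsv")
    write_design(design, out / "design.tsv")
    truth.table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if truth.responses is not None:
        truth.responses.to_csv(out / "responses.tsv", sep="\t", index=False)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a YAML-loaded mapping, tolerating lists for
    tuple-valued fields."""
    kwargs = {}
    for f in SimulationConfig.__dataclass_fields__.values():
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    unknown = set(d) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)
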