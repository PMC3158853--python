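import numpy as np
import pytest

import xicquant as xq


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free single run: 20 peptides, no jitter, unit scale — the
    parameter-recovery oracle."""
    cfg = xq.SimulationConfig(n_peptides=20, gradient_length=12.0,
                              noise_sigma_log=0.0, run_scale_range=(1.0, 1.0),
                              mz_jitter_ppm=0.0, tR_jitter_sd=0.0, rng_seed=7)
    run, truth, peptides = xq.simulate_run(cfg)
    return cfg, run, truth, peptides


@pytest.fixture(scope="session")
def replicate_dataset():
    """Six replicates of 60 peptides with lognormal noise, per-run scales
    and one injected outlier replicate (index 1)."""
    cfg = xq.SimulationConfig(n_peptides=60, gradient_length=15.0,
                              noise_sigma_log=0.198, rng_seed=3)
    runs, truth, peptides, design = xq.simulate_replicates(
        cfg, 6, xq.OutlierSpec(run_index=1))
    heights, areas, results = xq.quantify(runs, peptides)
    return dict(cfg=cfg, runs=runs, truth=truth, peptides=peptides,
                design=design, heights=heights, areas=areas, results=results)


@pytest.fixture(scope="session")
def mixing_dataset():
    """Five-point mixing series, 40 responsive peptides, mild noise."""
    cfg = xq.SimulationConfig(n_peptides=40, gradient_length=15.0,
                              noise_sigma_log=0.04, rng_seed=21)
    runs, truth, peptides, design = xq.simulate_mixing_series(cfg)
    heights, areas, results = xq.quantify(runs, peptides)
    totals = {r.run_id: r.total_ms1_intensity for r in runs}
    norm, _ = xq.normalize_total(heights, totals)
    pom, _ = xq.percent_of_max(norm)
    return dict(cfg=cfg, runs=runs, truth=truth, peptides=peptides,
                design=design, heights=heights, pom=pom)


def single_peak_run(mzs, intensities_by_scan, times):
    """Hand-built run: same centroid m/z list in every scan with per-scan
    intensities."""
    scans = []
    for t, intens in zip(times, intensities_by_scan):
        order = np.argsort(mzs)
        scans.append(xq.Ms1Scan(t, np.asarray(mzs, float)[order],
                                np.asarray(intens, float)[order]))
    return xq.MsRun("manual", scans)
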