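# xicquant

Identification-driven, label-free quantification of (phospho)peptide ions
from MS1 extracted ion chromatograms — plus the simulation and statistics
needed to characterise how precise, linear and accurate such measurements
are.

## The problem

In data-dependent LC–MS/MS, which peptides get fragmented and identified
is stochastic: replicate runs of the same sample identify overlapping but
different peptide lists ("undersampling"), even though the MS1 signal
itself is reproducible. For label-free quantification — especially of
phosphopeptides, which are scarce and matter individually — the remedy is
to quantify by *targeted extraction*: collect every confidently identified
peptide ion into a database (sequence, modifications, charge z, retention
time tR, mass), then extract its signal from **every** run's survey scans,
identified there or not.

`xicquant` implements that engine. For each peptide ion it builds
extracted ion chromatograms (XICs) for the first three isotopes and
accepts a quantification only when it passes three gates:

* **m/z**: centroids within a closed ±7 ppm window around each isotope's
  own theoretical m/z (envelopes computed by convolving per-element
  isotope abundances);
* **tR**: scans within ±5 min of the database retention time;
* **isotope distribution**: Pearson r > 0.95 between observed apex
  intensities and the theoretical envelope.

Peak height (apex of the summed three-isotope trace) and area
(trapezoidal integral between 5%-of-apex bounds) are reported per peptide
per run; absent signal is NA, never zero. Intensities are then normalized
to each run's total MS1 chromatogram intensity and expressed as a
percentage of each peptide's maximum across samples. Replicate outliers
are flagged (median |log2 ratio| to the consensus profile > 1) and removed
only on explicit confirmation.

Measurement quality is evaluated the way method-characterisation studies
do it:

* **precision** — per-peptide coefficient of variation across replicates,
  CV = 100·sd/mean;
* **linearity** — per-peptide OLS of intensity on the mixing proportion of
  a stimulated extract (e.g. 0/25/50/75/100% pervanadate-treated mixed
  with untreated), R² with the exact small-sample significance cutoff
  (critical r = 0.878 at n = 5, p < 0.05);
* **accuracy** — %Acc = |fitted − observed|/observed · 100 per dilution
  point, averaged.

Because public raw data are rarely re-runnable at desk scale, the package
ships a ground-truthed LC-MS1 simulator (Gaussian elution peaks ~30 s at
base, 2.5 s survey-scan interval ⇒ ≥10 points per peak, three-isotope
envelopes, lognormal replicate noise, per-run scale factors, outlier
replicates, flat background peptides) so the whole pipeline is testable
end to end. See `docs/methods.md` for the model and all defaults.

## Worked example

Simulate a five-point mixing series (50 responsive phosphopeptides rising
linearly from 20 to 100 units, 4% lognormal noise, per-run scale factors),
quantify, normalize, and evaluate linearity and accuracy:

```python
import xicquant as xq

cfg = xq.SimulationConfig(n_peptides=50, noise_sigma_log=0.04, rng_seed=42)
runs, truth, peptides, design = xq.simulate_mixing_series(cfg)

heights, areas, log = xq.quantify(runs, peptides)          # every pair attempted
norm, _ = xq.normalize_total(
    heights, {r.run_id: r.total_ms1_intensity for r in runs})
pom, _ = xq.percent_of_max(norm)

lin = xq.linearity_table(pom, design)
acc = xq.accuracy_table(pom, design, lin)
resp = [i for i in lin.index if not i.startswith("bg")]
print(f"accepted {sum(r.accepted for r in log)}/{len(log)} peptide-run pairs")
print(f"median R^2 (responsive): {lin.loc[resp,'r_squared'].median():.3f}")
print(f"significant at p<0.05:   {int(lin.loc[resp,'significant'].sum())}/{len(resp)}")
print(f"mean %Acc (responsive):  {acc.loc[resp,'mean_pct_acc'].mean():.2f}%")
```

prints

```
accepted 500/500 peptide-run pairs
median R^2 (responsive): 0.996
significant at p<0.05:   50/50
mean %Acc (responsive):  3.24%
```

Every peptide was quantified in every run (targeted extraction leaves no
missing cells here); the median dilution-series R² of 0.996 and mean
accuracy deviation of 3.2% show the pipeline recovering the injected
linear responses to within the 4% noise that was simulated. The first
rows of the linearity table carry the fitted slope/intercept per peptide,
the n-specific critical r (0.878 for 5 points) and the log2 fold between
the fitted endpoints:

```
            slope  intercept  r_squared  critical_r  significant  log2_fold
peptide_id
pep0000     0.822     15.403      0.994       0.878         True      2.663
pep0001     0.780     17.912      0.988       0.878         True      2.420
pep0002     0.788     21.480      0.999       0.878         True      2.224
```

The same flow is available from the shell, reading/writing mzML and TSV:

```sh
xicquant simulate --config mixing.yaml --out sim/
xicquant quantify --mzml sim/ --db sim/peptides.tsv --ppm 7 --rt-window 5 \
    --iso-corr 0.95 --out quant
xicquant normalize --matrix quant_height.tsv --totals quant_totals.tsv \
    --out norm.tsv --report norm_report.tsv
xicquant outliers --matrix quant_height.tsv --design sim/design.tsv
xicquant qc linearity --matrix norm.tsv --design sim/design.tsv --out report/
xicquant run-all --config mixing.yaml --out demo/     # the whole chain
```

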