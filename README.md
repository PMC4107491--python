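# mirserum

Pre-analytical quality control and analysis for serum miRNA qRT-PCR panels.

Circulating miRNAs are promising non-invasive biomarkers, but serum
quantification is fragile before any biology enters: red-cell lysis during
blood draw releases blood-cell miRNAs into serum, extraction efficiency can
drift, plates carry offsets, there is no agreed endogenous control, and
low-abundance reactions are noisy enough that naive fold-change calls are
dominated by technical error. `mirserum` implements the QC workflow that
addresses each of these, end to end:

* **Hemolysis**: spectrophotometric hemoglobin by the Harboe method,
  Hb [g/l] = (167.2·A415 − 83.6·A380 − 83.6·A450)/1000, classification at
  0.1 g/l, and a matched-pair screen that flags blood-cell-derived assays
  (≥3-fold up in ≥50% of lysed/unlysed pairs, or detected below Ct 34 in
  half the lysed samples and in no matched unlysed sample), plus a
  BH-controlled hemoglobin-correlation screen.
* **QC filters and calibration**: melting-curve and negative-control
  exclusion, the Ct > 35 reaction ceiling, the 80% detection-fraction rule
  (Ct < 34 presence calls), inter-plate calibrator normalization, and an
  exogenous spike-in check for extraction efficiency.
* **Endogenous-control selection**: within-pair ratio stability
  (2^(Ct_first − Ct_second) < 2 in every pair, ranked by ratio SD) for
  matched designs, and cross-cohort ranking by the SD of 2^(−Ct) over
  ubiquitously detected assays, global mean included for comparison.
* **Differential analysis**: ΔCt = reference Ct − assay Ct, fold change
  FC = 2^(ΔCt_case − ΔCt_control), a fold-change cutoff *calibrated* from
  technical replicates (smallest threshold whose technical false-call
  fraction fits a 10% budget — 3-fold under serum-panel noise), exact
  small-sample Mann–Whitney tests with Benjamini–Hochberg control, Pearson
  covariate screens, UPGMA clustering on 1 − r distances, and
  within-person longitudinal concordance.
* **Synthetic cohorts**: a generator that emulates the whole measurement
  process — 742-assay panel with planted reference, blood-cell and spike-in
  assays, Ct-dependent replicate noise with detection censoring, hemolysis
  dose–response, plate offsets — so the entire pipeline is testable without
  external data.

## Worked example

Simulate a matched lysed/unlysed cohort (10 volunteers, two vials each, one
mechanically lysed) and run the hemolysis analysis:

```python
import mirserum as m
from mirserum import pipelines

design = m.default_panel()
spec = m.CohortSpec(design=design, scenario="hemolysis_pairs", n_subjects=10)
cohort = m.generate_cohort(spec, seed=7)

results = pipelines.run_hemolysis(
    cohort.ct, cohort.samples, ipc=cohort.ipc,
    spike_assay=design.spike_in_assay,
)
print(results["spike_in_check"])
print(results["hemolysis_screen_summary"])
print(results["cluster_summary"])
```

which prints:

```
Spike-in check: PASS
  Mann-Whitney two-sided P = 0.970; median Ct difference = -0.01 cycles
  group medians: 23.31 vs 23.32 (n = 10, 10)
Hemolysis sensitivity screen
  pairs: 10; assays screened: 741
  fold-change cutoff: 3
  >= 3-fold up in all pairs: 125
  >= 3-fold up in >= 1 pair: 138
  >= 3-fold down in >= 1 pair: 11
  flagged: 162 (fold change 126, lysed-only detection 36, both 0)
Average-linkage Pearson clustering of 20 samples
  top split: 9 vs 11 samples
```

Reading the numbers: the spike-in Ct does not differ between lysed and
clean samples, so extraction efficiency is unaffected and the differences
the screen finds are genuine abundance changes. The screen flags 162
assays — exactly the panel's planted blood-cell-derived set: 126 through
the fold-change rule and 36 that appear only in hemolysed serum. The top
cluster split is 9 vs 11 rather than 10 vs 10 because the mildest
hemolysed sample (0.15 g/l, just over the threshold) sits with the clean
samples: profiles cluster by hemoglobin *level*, not by nominal group —
which is precisely why hemolysis screening has to precede biomarker work.

The same stages are available from the command line, one subcommand per
study design:

```
mirserum simulate --scenario hemolysis_pairs --subjects 10 --seed 7 --out sim/
mirserum hemolysis --ct sim/ct_matrix.csv --samples sim/sample_sheet.csv \
    --ipc sim/ipc.csv --plates sim/ct_matrix.plates.csv \
    --spike cel-spike-39 --out results/
mirserum calibrate-cutoff ...   # fold-change cutoff from technical replicates
mirserum endogenous-controls ...  mirserum fasting ...  mirserum smoking ...
mirserum longitudinal ...
```

Reports are deterministic for a given seed and carry the run-configuration
hash.

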