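# shrnakit

Short hairpin RNAs (shRNAs) can trans-activate promoter reporters in
transient transfection assays in a way that is **sequence-specific but
independent of the shRNA's target gene** — a confounder for anyone using
luciferase or fluorescent reporters to study transcriptional regulation.
Characterizing this off-target behaviour quantitatively takes a small
zoo of analyses: spike-in-calibrated miRNA count normalization, paired
differential-expression (DE) testing with fold-change thresholds, reporter
assay scoring across three readouts, structural analysis of the hairpin
oligos themselves, and integration of DE sets with miRNA target maps and
gene-family annotations.

`shrnakit` implements that workflow as a tested, reusable Python library,
exercised end-to-end on synthetic data with planted effects so every
estimator can be checked against its generative truth.

## What it computes

**Spike-in normalization.** Hybridization counters carry positive-control
RNAs (POS_B..POS_E) at known, decreasing concentrations. An OLS line of raw
counts on concentration gives each sample a hybridization slope and a
background signal *B*; each miRNA's raw count *Rᵢ* becomes

&nbsp;&nbsp;&nbsp;&nbsp;*Eᵢ = (Rᵢ − B) / slope*

in concentration units (clipped at 0), followed by global normalization
(every sample rescaled to the grand mean over all miRNAs).

**Paired DE.** Samples are paired across conditions by shared time point
(15/24/48 h). Per feature: a classical paired *t*-test on log2 values
(df = pairs − 1), a **signed linear fold change** (ratio *r* for *r* ≥ 1,
−1/*r* otherwise), and strict threshold calling — miRNAs at *p* < 0.05,
|FC| > 1.1; genes at *p* < 0.1, |FC| > 1.25.

**Reporter scoring.** Relative luciferase activity = mean RLU ratios with
delta-method SEs, chaining exactly (vs-control ÷ vs-control(reference) =
vs-reference); flow cytometry composite = %positive × median positive
intensity relative to an untransfected-control threshold (0.999 quantile);
qPCR via ΔΔCt against a reference gene (default GAPDH, efficiency 2).

**Hairpin structure.** pLKO.1 oligos (`CCGG` + sense + `CTCGAG` + antisense
+ poly-T) are decomposed exactly, stems checked base-by-base against the
reverse complement, mutant series compared by Hamming distance. A
transcribed 30-construct reference table ships with the package.

**Integration.** DE-set overlaps with direction concordance, miRNA-target ∩
DE-gene intersection annotated for repression consistency, gene-family
over-representation (upper-tail hypergeometric, percent to 2 dp), and R².

## Worked example

```python
from shrnakit import reporter, synthetic

plate = synthetic.simulate_reporter_plate(
    {"crxnrl": 10.23, "sh49": 88.0}, noise_cv=0.1, n_wells=4, seed=11, days=(2,)
)
vs_ctrl = reporter.relative_activity(plate, "sh49", "control", day=2)
vs_ref  = reporter.relative_activity(plate, "sh49", "crxnrl", day=2)
print(f"sh49 vs control:  {vs_ctrl.ratio:6.1f} +/- {vs_ctrl.se:.2f} (SE)")
print(f"sh49 vs CRX/NRL:  {vs_ref.ratio:6.2f} +/- {vs_ref.se:.2f} (SE)")
```

prints

```
sh49 vs control:    85.9 +/- 6.40 (SE)
sh49 vs CRX/NRL:    8.08 +/- 0.41 (SE)
```

i.e. with plate noise the planted 88-fold activation over the control is
estimated at 85.9-fold, and the same shRNA gives ~8-fold more activity than
the CRX/NRL transcription-factor condition alone (exactly 88/10.23 = 8.6 at
zero noise). The `examples/` directory has one short script per capability
(normalization, DE, reporter scoring, hairpin structure, full pipeline);
each prints what it computes and what the numbers mean. The end-to-end
pipeline is also available from the shell:

```bash
shrnakit run-all --seed 42 --out results/
```

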