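# dopaq

Quantification of trauma-induced dopaminergic neurodegeneration and
subcellular oxidative stress in *C. elegans* from large-particle
flow-cytometry (COPAS) data — together with the transcriptomic set logic and
promoter-scan transcription-factor screen that accompany such studies, and a
synthetic-data generator that stands in for live worm populations.

## Who this is for

Labs that measure per-worm fluorescence on a COPAS-class sorter and need a
reproducible, scriptable version of the spreadsheet-and-Prism workflow:
marker gating of mosaic transgenic populations, ratiometric redox-sensor
quantification, neurodegeneration indices, robust outlier removal, and the
downstream RNA-seq/qPCR/motif-screen arithmetic.

## The statistics at the core

**Oxidation ratio.** Strains carrying a ratiometric peroxide sensor
(roGFP2-ORP1) as a non-integrated (extrachromosomal) array are mosaic: the
mCherry-negative worms of the same run carry no transgene and define the
autofluorescence background. For each transgene-positive (mCh+) worm *i* of a
condition:

```
ratio_i = (405_i − mean 405_mCh−) / (mean 488_mCh+ − mean 488_mCh−)
Oxidation ratio = mean(ratio_i | injured) − mean(ratio_i | uninjured, time-matched)
```

Oxidation of the sensor shifts excitation from 488 nm toward 405 nm, so a
positive oxidation ratio reports injury-induced peroxide accumulation.

**Dopaminergic GFP index.** Per-worm GFP *retention* is the injured worm's
head GFP peak (the maximum over the leading 20% of the axial profile) divided
by the mean uninjured head GFP peak of the same genotype/RNAi arm. With
control and test arm retention means `cΔ` and `tΔ`:

```
index = (cΔ − tΔ) / (cΔ − 1)
```

`index > 0` means the test condition protects dopaminergic neurons relative
to control; `index < 0` means it worsens degeneration.

Around these sit: exact between-class-variance gating of the mCherry marker
in log space, ROUT outlier removal at Q = 1% (robust location fit → RSDR →
FDR-controlled flagging), Welch/ANOVA contrasts with Šidák or Dunnett
adjustment, RPKM normalization, DEG set subtraction with hypergeometric
enrichment, ΔΔCt qPCR quantification with multi-melt-peak well exclusion, and
a both-strand PWM log-odds promoter scan feeding a four-criterion TF
candidate filter.

## Worked example

```python
import numpy as np
import dopaq
from dopaq.flow import Condition
from dopaq.metrics import GfpIndexModel

mk = lambda ret, seed, tr: dopaq.simulate_copas_population(
    dopaq.PopulationParams(n_worms=2000, mosaic_rate=1.0, true_retention=ret, seed=seed),
    Condition(treatment=tr))

model = GfpIndexModel(
    control_injured=mk(0.6, 1, "injured"), control_uninjured=mk(1.0, 2, "uninjured"),
    test_injured=mk(0.9, 3, "injured"),    test_uninjured=mk(1.0, 4, "uninjured"))
res = model.fit(n_boot=200, seed=0)
print(res.summary())
```

prints

```
                               value
gfp_index                   0.762513
control_retention_delta     0.596135
test_retention_delta        0.904087
ci95_lo                     0.704036
ci95_hi                     0.814124
n_control                2000.000000
n_test                   2000.000000
n_bootstrap               200.000000
```

The control arm was simulated with 60% GFP retention after injury and the
test arm with 90%; the fitted retention deltas recover both, and the index
lands on the analytic value (0.6 − 0.9)/(0.6 − 1) = 0.75 — the test
perturbation is protective. The CI comes from resampling worms within each of
the four populations.

The same end-to-end flow, driven by a config file, runs from the shell:

```sh
dopaq run --config my_run.yaml        # or with no --config: the packaged demo
```

The demo run simulates mosaic sensor populations (planted 405/488 shift 0.5)
and reporter populations (planted retention 0.6 vs 0.9), gates them, and
writes tidy provenance-stamped tables; its `oxidation.tsv` reports an
oxidation ratio of 0.4996 and its `gfp_index.tsv` an index of 0.6818
(n = 800 per population at the demo seed).

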