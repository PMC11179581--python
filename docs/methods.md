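# Methods

## The measurement model

A COPAS-class large-particle flow cytometer records, per worm, an extinction
peak, a time of flight and per-channel fluorescence peak heights; optionally
an axial intensity profile of the GFP channel along the body. Two assay
families are quantified:

* **Redox sensing.** The sensor strains carry roGFP2-ORP1 on
  extrachromosomal arrays, which are inherited mosaically: a fraction of
  each population is transgene-negative and supplies an internal
  autofluorescence blank. The sensor's excitation shifts from 488 nm toward
  405 nm upon oxidation, so the background-corrected 405/488 ratio of the
  mCherry-positive events, referenced to time-matched uninjured controls,
  reports injury-induced peroxide accumulation (`oxidation_ratio`).
* **Neurodegeneration.** The reporter strains carry integrated dopaminergic
  GFP, so every worm is a carrier. Per-worm GFP retention — head GFP peak
  over the mean uninjured head peak of the same arm — is a proxy for neuron
  survival, and the GFP index `(cΔ − tΔ)/(cΔ − 1)` places a test arm's
  injury-induced loss on a scale where 0 is "same as control" and 1 is
  "fully protected".

The formula for the oxidation ratio mixes a per-event numerator with
condition-level means. We evaluate it per event — each mCh+ worm's 405 signal
minus the condition's mCh− 405 mean, over the condition-level difference of
488 means — then average. This reading keeps per-worm values available for
outlier removal and confidence intervals; the ratio-of-means alternative
(identical condition mean) is available via `per_event=False`. Similarly,
`retention_delta` is the mean of per-worm retentions; with the per-condition
divisor fixed this equals the ratio of means, and the per-worm form is what
ROUT and CIs operate on. Negative background-corrected values are retained,
not clipped: clipping would bias condition means upward, and gross negatives
are ROUT's job.

The GFP-index CI is a seeded nonparametric bootstrap (default 2000
resamples; the demo config uses 200) resampling worms independently within
each of the four underlying populations. The assay itself defines no CI for
the index, so this is a package choice, recorded in every output.

## Gating

The marker threshold maximizes between-class variance of log-transformed
mCherry intensities. The criterion is evaluated exactly over all n−1 split
points of the sorted sample rather than over a binned histogram, which makes
the classification exactly equivariant under rescaling all intensities by a
common factor (a gain change). The boundary value itself is assigned to the
negative class (strict `>` for positive). The estimator refuses constant
input ("unimodal") and fewer than 10 values; a user-supplied constant
threshold can always be passed to `gate_mcherry` instead.

Axial profiles are oriented head-first: the head is the end whose leading
20% window contains the global maximum (falling back to the larger end-window
maximum, with a lexicographic tie-break so orientation never depends on the
input's direction). The head peak is the maximum over the first
`ceil(head_fraction · n_bins)` bins, `head_fraction` defaulting to 0.20.
When no profile is stored, `gfp488_peak` is treated as the already-extracted
head peak, matching instruments that perform partial-profile extraction
on-board.

## ROUT outlier removal

Specialized to the one-sample case (per-worm metric columns), at maximum
outlier FDR Q = 0.01 by default:

1. robust location by iteratively reweighted estimation with Tukey's
   biweight (c = 4.685), initialized at the median, scale refreshed from the
   MAD each iteration; `max_iter = 100`, `tol = 1e-8`;
2. RSDR = 68.27th percentile of absolute residuals, scaled by N/(N−1);
3. per-point two-tailed p from t = |residual|/RSDR with N−1 df;
4. Benjamini–Hochberg step-up flagging at rate Q (largest residuals first).

Below n = 10 nothing is removed and a `small_n` flag is set — FDR control is
not meaningful at tiny n, and silent behavior would be worse than a warning.
Identical inputs give RSDR 0 and no removals. Flags are invariant under
affine transforms of the data.

## Group comparisons

`compare_two` is Welch's unequal-variance t with the 95% CI of the mean
difference. `anova_with_adjustment` computes planned pairwise contrasts on
the pooled within-group variance (one-way decomposition) with Šidák
adjustment `1 − (1−p)^m`, or many-to-one Dunnett comparisons via the
multivariate-t distribution (scipy's implementation, which handles unequal
group sizes directly). Šidák CIs are reported at the Šidák-adjusted
per-comparison confidence.

## Transcriptomic arithmetic

RPKM is `counts · 1e9 / (length · library size)`. Control-relative scaling
is `mean(treated)/mean(control) − 1`, so control maps to 0. `call_deg` is a
deliberately simple, documented stand-in for a dedicated DE pipeline: a
pooled-variance two-sample t on log2(RPKM + 1) per gene (groups are small,
equal-sized and share a single dispersion in the generating model, so the
equal-variance form keeps its degrees of freedom where Welch's Satterthwaite
approximation would collapse them), BH adjustment across genes, and flags at
adjusted p ≤ 0.05 and |log2FC| ≥ 1 by default. All set-logic operations are
defined over whatever DEG tables are supplied, so externally produced tables
(e.g. a commercial workbench's exports) drop in unchanged. BH is used for
gene- and category-level families; Šidák/Dunnett are reserved for worm-level
contrasts.

ΔΔCt aggregates the two reference genes (`tba-1`, `Y45F10D.4` by default) by
the arithmetic mean of their mean Cts — the geometric mean of their
expression, standard multi-reference practice; the aggregation is
switchable. Wells with more than one melt peak never contribute.

## TF candidate screen

Binding-site prediction is an explicit PWM log-odds scan (counts +
pseudocount 0.25 per cell, columns normalized, scored in log2 against a
uniform background) over both strands, skipping windows containing N. The
default site threshold is 0.8 of each motif's maximum achievable score — a
declared stand-in for an external web predictor whose threshold is not
reproducible. The filter keeps a TF iff TFT rank ≤ 50, mouse and worm
homologs annotated, dopaminergic expression annotated, and ≥ 1 predicted
site in the 4 kb window upstream of the TSS; survivors are ranked by site
count, ties broken by TFT rank. Homology and expression flags are inputs,
never inferred.

## The synthetic-data generator

Channel model: strictly positive, right-skewed lognormal transgene signal
plus additive Gaussian autofluorescence truncated at zero (defaults:
GFP log-mean 5.0, log-sd 0.4; autofluorescence means 1–2 a.u., sd 0.5).
The distributional family of real COPAS peak heights is not published; the
lognormal is an assumption, documented here, not an inference about the
instrument. Non-carriers show autofluorescence in every channel. Oxidation
is planted as a shift of the background-corrected 405/488 ratio (baseline
0.4), i.e. in exactly the units `oxidation_ratio` estimates; injury scales
carrier GFP by `true_retention`. Agitation settings (16 s, 8600 rpm) are
carried as inert provenance metadata and never used in computation.
Compartment kinetics are piecewise-linear templates (matrix: rise within
minutes, resolved by 2 h; outer membrane: peak at 2 h; cytosol: late rise,
elevated through 24–48 h) — qualitative configuration, not fitted values.

Sensor populations default to `mosaic_rate = 0.6` (extrachromosomal
transmission); retention/index simulations use `mosaic_rate = 1.0` because
the corresponding reporter strains carry integrated arrays — an ungated
mosaic would add carrier-fraction binomial noise the real assay does not
have.

The DEG generator draws gamma-Poisson counts (dispersion 0.05, 4 replicates
per group) with planted ±`effect_log2fc` on the designated truth sets.
Baseline means are lognormal(log 500, 0.8) floored at 20 counts: the
generator's contract is that planted truth is recoverable downstream, and
unfloored low-expression genes have their planted fold changes compressed
below the |log2FC| threshold by the RPKM pseudocount — that failure mode
tests the pseudocount, not the set logic.

What the generator does **not** emulate: raw COPAS waveforms, optics or PMT
behavior, doublets/debris, batch effects between biological replicates,
gene-length or GC bias in counts, qPCR efficiency differences from 2.0, and
promoter sequence composition beyond i.i.d. GC content. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every artifact of real instruments.

## Determinism and problem sizes

Every generator takes one integer seed; sub-streams derive from it via
`numpy.random.SeedSequence`, so fixed seeds reproduce outputs byte for byte
and the pipeline is a pure function of (config, seed). Verification runs use
populations of 500–2000 worms, 200 replicate null simulations for ROUT
calibration, 1000-gene DEG experiments, and 10 kb scan sequences — sizes at
which planted-parameter recovery tolerances (±0.02 on retention, ±0.05 on
the index and oxidation ratio) sit several standard errors wide of the
estimators' sampling noise.

## Known limitations

* The oxidation ratio presumes the mCh− blank is drawn from the same
  autofluorescence distribution as the carriers' background — true for
  mosaic siblings on the same plate, not necessarily across plates.
* `call_deg` makes no attempt at count-model shrinkage; it is not a
  replacement for DESeq2/edgeR on real data.
* Dunnett CIs use scipy's implementation; no exact agreement with any
  commercial package's numerics is claimed, only with the method definition.
* The PWM scan reports raw hit counts; it does not model site clustering,
  chromatin accessibility or conservation.
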