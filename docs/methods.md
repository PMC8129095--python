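# Methods

This note documents the models, rules and numerical choices behind
`lfpexcite`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the analysis recipe was genuinely open.

## Spectral metrics

Power spectra are averaged modified periodograms (Welch's method:
Hann taper, `window_s = 2` s, 50 % overlap, `scipy.signal.welch` with
density scaling), giving 0.5 Hz resolution on the final 60 s of each
recording. The estimator choice is a design decision — variance reduction
at a resolution fine enough to localise a gamma peak to half a hertz;
absolute power values are therefore estimator-relative, and every check in
the test suite is either scale-invariant or computed against the same
estimator.

- **Gamma peak** (20–80 Hz): among in-band local maxima with power at least
  `rel_height = 0.5` of the in-band maximum, the lowest-frequency one is
  returned. The rule exists because slices at high agonist concentrations
  can express a second, faster rhythm; the analysis convention is to track
  the lower gamma peak. `rel_height` is configurable; 0.5 keeps genuine
  secondary peaks while ignoring shoulder bins.
- **Area power**: trapezoidal integral over 15–48 Hz with linear
  interpolation at the band edges, so the integral is exactly additive over
  adjacent sub-bands.
- **Clear-gamma gate**: a trace is included in spectral group statistics at
  a concentration only if its in-band peak is at least `snr_min = 5` times
  the median power over 1–300 Hz outside the band. The underlying judgement
  was originally visual; 5× the out-of-band median accepts every simulated
  oscillating trace and rejects pure noise essentially always (tested over
  seeded repetitions). Gated-out rows are excluded *per level*, not per
  slice, and still contribute to event statistics.

## Event detection

The final-minute segment is mean-subtracted and z-scored against its own
standard deviation (plain sample SD, `ddof = 1`; a robust 1.4826 × MAD
option exists because large discharges inflate the plain SD — the default
follows the plain-SD convention). Excursions with |z| ≥ `k_spike = 5` in
either direction are events. Crossings closer than `merge_window_ms = 200`
merge into one candidate, so one multiphasic discharge is not counted
several times; a candidate is an **IID** iff its peak |z| ≥ `k_iid = 10`
and its above-threshold envelope (first to last crossing) spans ≥
`iid_min_width_ms = 40`, else a **spike**; a `refractory_ms = 20` minimum
separation is enforced between distinct events. Every event is exactly one
of spike/IID, and the detector is deterministic for fixed input.

The IID rule is an explicit operational surrogate for what is, in practice,
a manual call by an electrophysiologist. Its parameters are exposed in
`DetectorConfig`, and all recovery claims are made against the simulator's
ground truth only — the package does not claim the rule reproduces any
particular expert's labels.

## Slice classification and statistics

Per concentration: any IID → *interictal activity*; otherwise a spike count
**strictly greater** than mean + 2 SD (sample SD) of the wild-type counts at
that concentration → *high spikes*; otherwise *no abnormal activity*. The
strict inequality and the n−1 SD are deliberate and tested to 1e−12 on
hand-computed vectors.

The two-way mixed ANOVA (between = genotype, within = concentration,
subject = slice) is computed by sequential least-squares sums of squares
with a subject error stratum: the between effect is tested against the
subject-within-genotype mean square, the within and interaction effects
against the residual. On balanced data this reduces to the classical
partition (verified against both a closed-form oracle and
`pingouin.mixed_anova` to 1e−6); with cells removed by the clear-gamma gate
the sequential fit degrades gracefully instead of dropping whole slices —
exclusion is per missing level, a documented choice. Transforms: `log10`
(requires positive dv; used for area power) and `rank` (joint mid-ranks
over all observations, Conover-style, hence invariant under any strictly
monotone transform of the dv; used for event rates). A constant dv yields
F = 0, p = 1. No sphericity correction is applied (none is claimed by the
analysis this mirrors). Normality routing uses Shapiro–Wilk at α = 0.05;
samples too small for the test (n < 3) default to the parametric branch,
and constant samples route non-parametric. α = 0.05, two-sided, throughout.

## Transcriptomics

BH adjustment is delegated to `statsmodels` (`fdr_bh`) behind `bh_adjust`;
the test suite checks it exhaustively against a literal step-up oracle on a
fixed p-value grid. Significance is padj ≤ 0.05 (boundary included).

**RRHO**: both tables are ranked by descending log2 fold change; for grid
thresholds i, j (multiples of `step`, default round(N/100)), the cell value
is −log10 P[X ≥ o] with X ~ Hypergeometric(N, i, j) and o the top-i/top-j
overlap. This is the one-sided enrichment map over the concordant
(both-upregulated) corner; no signed two-sided variant is computed. The
tail is evaluated exactly by `scipy.stats.hypergeom.sf` (log-space
internally) and verified against integer-rational brute-force summation to
1e−9. The summary statistic is the sum of the map. The permutation p value
permutes the gene-to-logFC assignment of one table — with only a handful of
biological samples behind each table, a sample-level permutation is
ill-defined downstream of the DE fit, so the exchangeable gene-label null
is used and documented as such; permuting one list's labels is implemented
as drawing a uniform random ranking. The estimate is add-one,
(1 + #{perm ≥ obs})/(n_perm + 1), so it is never zero; default
n_perm = 999. Tables with different gene universes are inner-joined with a
logged count of dropped rows.

**KS term enrichment**: per term, a two-sample Kolmogorov–Smirnov test of
member scores against non-member scores. The default score is the raw DE
p value (unsigned), i.e. the question is "are this term's genes
differentially expressed", not "are they coherently up"; the scored
variable is caller-configurable. Terms with fewer than 2 members or
non-members in the scored universe are skipped with a warning.

## Bench assays

qPCR expression is 2^−(Ct_GOI − Ct_Normaliser); undetected wells stay
missing (no Ct-ceiling imputation) and are excluded from means with
reported counts — when no wild-type well detects the transcript, the fold
change is reported as undefined rather than invented. Fold change is the
ratio of group means of 2^−ΔCt (normalise first, then compare), tested with
a two-sided Student's t-test; a configurable switch tests ΔCt values
instead, since either convention is defensible. Luciferase wells are
firefly/renilla ratios scaled to 100 × the control-mimic mean within each
construct (the control group averages exactly 100 % by construction). Blot
intensities are target/GAPDH per lane. Zero-variance group comparisons are
flagged degenerate rather than returning a meaningless p.

## Synthetic data: what it emulates, and what it does not

`simulate_trace` builds: band-limited (1–300 Hz Butterworth, mirroring the
recording hardware's analogue filters) white Gaussian noise rescaled to
`noise_sd`, plus a gamma sinusoid, plus inserted transients — spikes are
biphasic difference-of-Gaussians (≈ 8 ms; trailing lobe 0.6× so the peak
sample, which ground truth records as the event time, is unambiguous), IIDs
a sharp transient followed by a 0.65-amplitude slow wave (≈ 80 ms total, so
the above-5-SD envelope comfortably exceeds the 40 ms duration criterion).
Events are placed with a 400 ms exclusion window so ground truth is
unambiguous. Noise filtering is padded by 1 s on each side to keep filter
edge transients out of the trace.

`simulate_cohort` uses the study-sized defaults: 2 genotypes × 6 mice ×
(3,3,3,3,2,2) = 16 slices, concentration ladder 0/50/100/150/200/400/600/
800/1000 nM, 5 kHz sampling. Only the analysed final minute of each
application step is synthesised — the preceding 29 minutes of each
application contribute nothing to any computed quantity. Gamma amplitude
follows A·c/(c + K)·exp(−c/c₀) with K = 150 nM and c₀ = 700 nM, a
saturating rise times an exponential collapse peaking near 400 nM — the
qualitative shape the assay shows; the functional form is a modelling
choice, not a measured curve. Event rates are per-genotype Poisson
intensities, constant across non-zero concentrations (no baseline events):
wild type 8 spikes/min and 0 IIDs/min, knockout 20 spikes/min and 0.5
IIDs/min. These defaults were set once from the summary statistics the
motivating experiment reports — P(≥1 IID in a minute at 0.5/min) ≈ 0.39,
near its ≈ 37.5 % interictal proportion, and Poisson(8) gives a mean + 2 SD
spike threshold near its worked-example value of 15 — and are not tuned
further.
Event amplitudes are specified in multiples of the *total* background SD,
sqrt(noise² + amp²/2), because the 5 SD detection threshold is measured on
the final-minute SD, which includes the oscillation; defaults are 8 SD
spikes and 14 SD IIDs, the latter set clear of the k_iid = 10 class
boundary because the measured SD is further inflated by the events
themselves. Real spike/IID amplitude and width distributions are not
available to match; these are calibration choices.

What the generator does **not** emulate: biophysical network dynamics,
1/f background structure, electrode drift, event-waveform variability
between slices, concentration-dependent event rates, or any coupling
between oscillation phase and event timing. Passing recovery tests
therefore shows the detectors and statistics are correct under their stated
assumptions — not that they would reproduce a particular expert's manual
scoring of real recordings.

`simulate_event_counts` draws the same per-slice Poisson counts without
waveform synthesis. The statistics-calibration checks (null uniformity of
the genotype-effect p over 500 cohorts; power at the default effect over
100 cohorts) run at this count level: the ANOVA consumes per-slice rates,
and the trace → detection path is validated separately by the detector
recovery and end-to-end checks. Null calibration uses 0.5 IID/min in both
genotypes (a zero-rate null would make the dv constant and the test
degenerate).

`simulate_de_study` defaults: 12 000 genes, 40 shared upregulated genes
(observed logFC = true ± N(0, 0.15), true effects N(1.5, 0.3)), 60
tissue-specific DE genes per tissue with random sign, null genes with
uniform p and N(0, 0.05) logFC, and a 400-gene predicted-target union
overlapping the shared set by round(0.15 × 40) = 6 — the candidate count
the motivating experiment reports. A single tissue-specific size parameter
cannot reproduce both of that experiment's per-tissue DE totals (126 and
81) at once; the structure (≈ 100 per tissue, 40 shared, 6 candidates) is
the reproducible quantity. Null genes are independent between tissues, so
cross-tissue concordance comes only from the shared set; the RRHO
permutation p on default tables is accordingly modest (∼10⁻²), not the
genome-wide-correlation value a real paired-tissue dataset shows.

`simulate_bench_tables`: normaliser Ct ≈ 20, gene of interest 5 cycles
later in wild type, knockout shifted by −log2(fold change) (default 2),
Gaussian cycle noise (SD 0.15); luciferase wells with the 5p-mimic arm
scaled by the repression factor (default 0.5, i.e. ≈ 50 % activity);
knockout blot bands scaled 1.5×.

## Problem sizes and tolerances

Tests and the acceptance script use: 100 seeded traces for detector
recovery (±10 ms matching) plus 100 noise-only traces for the
false-positive bound; 500/100 count-level cohorts for null/power
calibration; N = 50, step = 5 for the brute-force RRHO oracle (1e−9);
exhaustive BH verification for all grid p-vectors of length ≤ 8 (1e−12);
200 seeds for KS null uniformity; one full default cohort for the
end-to-end phenotype check. Hand-computed fixtures are asserted at 1e−12,
algebraic identities at 1e−9, stochastic recoveries at the rates stated in
the tests.

## Known limitations

- The mixed ANOVA's sequential sums of squares are exact for balanced data
  and a reasonable convention under mild, gate-induced missingness; heavily
  unbalanced designs would usually be fitted with a linear mixed model,
  which is out of scope here.
- The IID rule is a surrogate; its two parameters (k_iid, minimum width)
  interact with the SD inflation discussed above.
- RRHO is one-sided (concordant upregulation); discordance analysis would
  need the signed two-sided map.
- p values below ≈ 1e−308 underflow to 0 in the ANOVA table.
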