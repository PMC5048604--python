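# Methods

This note records the statistical model behind `adaptnipt`, the choices
made where the design was genuinely open, what the synthetic cohorts do and
do not emulate, and the package's known limitations.

## Model and pipeline

The pipeline consumes per-sample unique-read counts over fixed genomic bins
(0-based, half-open, at most 20 kb) restricted to autosomes 1–22, together
with each bin's GC fraction and a usability flag.  Sex chromosomes are
never scored; manifest rows for aneuploid, twin and outlier samples are
excluded from the reference panel as a set union (a twin trisomic sample is
excluded once).

**GC correction** is per sample and multiplicative: a degree-1 LOESS fit
L(gc) of usable-bin count on bin GC, with the corrected count
`count * M / max(L(gc), 0.01 M)` where M is the sample's mean usable-bin
count.  The clamp prevents blow-up where the fit approaches zero at extreme
GC.  Each sample gets its own fit because bias curves are sample-specific
(library preparation and sequencing chemistry vary per run).  The span
default is 0.3: the bias curves the corrector faces are unimodal over a GC
range of ~0.3–0.6, and a 0.75 span oversmooths them badly enough to leave
chromosome-level systematic residuals an order of magnitude above shot
noise for the GC-extreme chromosomes; 0.3 tracks the curvature while
keeping ≥ hundreds of bins in every local fit at realistic bin counts.
The fit uses a `delta` of 1% of the GC range (near-duplicate GC values are
interpolated), making correction effectively linear-time.

**Profiles.**  Corrected counts are summed per autosome (RC) and divided
by the autosomal total to give reads fractions Rf that sum to 1.  The
per-chromosome GC content is the count-weighted mean bin GC using the
*raw* counts: the quantity it proxies is the GC content of the reads as
sequenced, and weighting by corrected counts would flatten precisely the
between-sample GC signal the selection algorithm matches on.  A BAM-derived
per-read GC could be substituted upstream; the pipeline only requires that
the same definition be used for panel and test samples.

**Normalisation** divides each chromosome's fractions by their sum over
the N panel samples (so normalised columns sum to 1) and stores the column
sums, which are applied unchanged to test samples; a single test sample is
therefore scorable against a frozen panel.  No rescaling by N is applied —
z scores are invariant to any common per-chromosome scale.

**Scoring.**  Per target chromosome, ordinary least squares of normalised
fraction on GC content across the panel; a test sample's z is its residual
standardised by the panel residual mean and sample standard deviation
(ddof 1).  z > 3 corresponds to the euploid 99.9th percentile under
normality, and that single-cutoff rule is the default; the dual scheme
(negative below 2, positive above 4, gray zone between) is provided for
laboratories that prefer a retest band.  Cutoff boundaries resolve to the
less severe category (strict inequalities).

## Adaptive selection

For a test sample and target chromosome, candidate reference sets are
rectangular windows centred on (a) the test sample's chromosome GC content
and (b) its *fitted* reads fraction α + β·GC from the full-panel
regression.  The fitted centre matters: a trisomic sample's observed
fraction is inflated, and centring on it would drag the window toward
high-fraction references and dilute the very signal being tested.  Windows
are evaluated on the grid g ∈ {0.001, 0.002, …, 0.02} (GC half-width) ×
r ∈ {0.00005, …, 0.001} (normalised-fraction half-width); both units and
maxima are configurable.  The uniform multiplicative grid covers the
several stepping conventions a practitioner might choose and makes window
membership monotone in g and r by construction.

Among windows with at least `min_panel` members (default 30) the window
with minimal reads-fraction CV is selected, with two safeguards against
selection-on-noise, both of which are no-ops when the data are genuinely
heterogeneous:

* **One-standard-error rule.**  A CV estimated from n samples has standard
  error ≈ cv/√(2n); all windows within one SE of the minimal CV count as
  tied, and ties resolve to the largest membership (then smaller g, then
  smaller r, for determinism).  Without this, the argmin over ~400 nested
  noisy CV estimates is a winner's-curse estimator.
* **Moderated residual variance.**  The regression is refitted on the
  selected members, and the refit's residual variance is shrunk toward the
  full-panel residual variance with 60 prior degrees of freedom (as in
  moderated t statistics) before standardising the test residual.  When
  the chosen window is the whole panel the two variances coincide and the
  statistic reduces exactly to the baseline z, so disabling selection
  (unbounded windows) reproduces baseline scoring to machine precision.

Measured on the default synthetic conditions (396-sample panel, 3.3 M
reads), these two safeguards together reduce the euploid false-positive
rate of the adaptive z at the 3-cutoff from ~1.3% to ~0.3% without
changing trisomy sensitivity at fetal fractions ≥ 4%.

If no window reaches `min_panel`, the full panel is used with a logged
warning.  The grouping of positive samples into 0.01-wide GC regions and
the median-GC representative choice (lower median for even sizes; the
smaller sample id for two-sample groups) reproduce the cohort-evaluation
design; production calling treats every test sample as its own
representative.

Outlier flagging of panel samples uses a robust z (median / 1.4826·MAD per
chromosome, threshold 3 on any autosome).  This criterion is this
package's own construction and is configurable.

## Synthetic cohorts

The generator emulates the structure the method assumes, at a scale where
the full pipeline runs in seconds per cohort:

* **Genome.**  22 autosomes with bin counts proportional to hg19
  chromosome lengths, default 5,000 bins total; per-chromosome mean GC
  follows the hg19 ranking, affinely compressed so that, after per-sample
  bias, all per-chromosome GC contents stay inside a configured envelope
  (default 0.40–0.51).  Within-chromosome bin GC spreads ±0.11; ~1% of
  bins are unusable; bin efficiencies vary log-normally (sd 0.1).
* **Per-sample bias.**  A unimodal scaled-beta bias shape (random mode and
  amplitude) times an exponential GC tilt.  The tilt is the sample's
  latent "GC state": it shifts every chromosome's count-weighted GC.  The
  feasible tilt range is calibrated numerically against the envelope, and
  samples draw from an inner 80% fraction of it.
* **GC–fraction coupling.**  Each chromosome carries a fixed GC-response
  loading (partly its mean-GC deviation, partly an idiosyncratic ±1
  component standing for fine-scale composition that bin GC cannot see),
  and a sample's chromosome fractions are multiplied by
  exp((slope·t + curvature·(t²−1))·loading) with t the standardised tilt.
  The idiosyncratic part is essential: a loading proportional to mean GC
  alone is predictable from bin GC and gets absorbed by the LOESS
  correction, leaving nothing for panel selection to match.  The linear
  term (slope 0.01) gives the default cohort a full-panel chr21 CV of
  ~0.006 against a within-window ~0.0045; the quadratic term (0.02, on by
  default only in the stratified generator) is what a panel-wide *linear*
  regression cannot remove.
* **Noise.**  Negative-binomial counts via gamma–Poisson mixing,
  dispersion 0.0002 per bin at the default 5,000-bin/3.3 M-read scale.
  The value is calibrated so the full-panel chr21 CV lands at ~0.005–0.006
  — the plausible range for GC-corrected NIPT at this depth, where a fetal
  fraction of 4% maps to z ≈ 4, matching the field's framing of 4% as the
  reliability threshold.  Dispersion is a per-bin parameter: its variance
  contribution scales with per-bin depth, so it must be re-chosen if the
  genome scale changes substantially.
* **Trisomy.**  Target-chromosome intensities are multiplied by 1 + f/2;
  the twin flag halves f first (the unaffected co-twin's cfDNA dilutes the
  signal by ~50%).  Because fractions renormalise, the realised inflation
  of the chr21 fraction is (1 + f/2)/(1 + Rf₂₁·f/2) ≈ 1.0983 at f = 0.2
  rather than the idealised 1.10; tests allow for this ~0.13% denominator
  effect.
* **Stratified panels.**  Two subpopulations at asymmetric tilt centres
  (−0.5 and +0.8 of the tilt scale, sd 0.12) with the quadratic coupling
  switched on; generation verifies on the latent fractions that the full
  panel's chr21 CV exceeds every within-subpopulation CV.

What the cohorts do **not** emulate: fragment-level GC bias (per-read GC is
proxied by count-weighted bin GC everywhere), mappability structure,
maternal copy-number variants, mosaicism, or batch effects beyond the
per-sample bias curve.  Passing tests therefore demonstrate the method's
statistical behaviour under its stated model, not performance on any
clinical data.

## Calibration and test-scale choices

Euploid z calibration (the P(z > 3) ≈ 0.00135 property) is checked on a
GC-homogeneous cohort (tilt range restricted to 25%): under the full
default GC heterogeneity the residual variance is heteroscedastic across
the GC range, and a mixture of variances has heavier tails than any single
normal — measured ~0.002 at the 3-cutoff — so the common-variance normal
model the property asserts only holds in the homogeneous regime.  The
heterogeneous-tail behaviour is intrinsic to pooled-sd scoring and is one
of the reasons adaptive selection exists.

Problem sizes used by the test suite and acceptance script: 396-sample
panels on the 5,000-bin genome at 3.3 M reads; 20 stratified cohorts for
the CV-improvement property; 500 scored samples (half euploid, half
trisomy 21 with f ~ U(0.04, 0.20)) for separation; 20,000 scores for tail
calibration; 100–200 replicates elsewhere.  OLS recovery is asserted at
binomially consistent 3-SE coverage (≥ 97/100 panels, all within 4 SE),
since demanding all 100 inside 3 SE would fail a quarter of the time by
construction.

## Numerical notes and limitations

* LOESS predictions are linear interpolations of the fitted points; bins
  outside the fitted GC range take the nearest endpoint value.
* Degenerate inputs fail loudly: zero GC spread in a regression panel,
  zero residual sd, zero column sums, and empty groups raise typed errors;
  a degenerate GC spread at correction passes counts through with a
  warning rather than dividing by a flat fit.
* Region bucketing uses floor(gc/width) with a 1e−9 guard so exact
  boundaries (0.420) land in the region they open despite binary rounding.
* The method scores whole-chromosome representation only; it does not
  segment, does not estimate fetal fraction, and says nothing about
  sex-chromosome aneuploidy.
* Minimum window size 30 reflects the smallest reference set observed to
  behave acceptably in this setting; below that, residual-sd estimates are
  too noisy even with moderation.
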