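# Methods

`acidflux` models the computational workflow of a time-resolved
transcriptomic stress experiment on *Corynebacterium glutamicum*: two
low-pH regimes — an acute, unbuffered pH 4.0 shock sampled at 1 and 4 h,
and a sustained, pH-stat pH 5.5 stress sampled at 1, 8 and 18 h — each
compared against a pH 7.0 control at the same timepoint. This note
records the models, the parameters that matter, and the design choices
made where several defensible options existed.

## Growth kinetics

**Sliding-window μ_max.** OD600 is ln-transformed and an ordinary
least-squares line is fitted over every window of `window_size`
consecutive points (default 7, step 1). Regression always uses the
actual sampling times, so irregular series are handled exactly. The
exponential phase is the *first* contiguous run of windows with
R² ≥ `r2_threshold` (default 0.90); μ_max is the maximum slope among
those eligible windows, with ties broken by the earliest window. When a
later qualifying run exists it is flagged (`multiple_runs`) but never
used. If no window qualifies, μ_max is reported missing with a warning
rather than raised as an error — flat or chaotic cultures are a valid
observation, not a failure.

Windows with zero variance in ln OD (SST = 0) take R² = 1 when the
residuals are also zero, else 0. This avoids 0/0 and means a perfectly
constant window "fits a line perfectly"; its slope is 0, so it can
never set μ_max on a growing culture. One consequence worth knowing: on
an *idealised noiseless* curve with a mathematically flat lag plateau,
the plateau windows qualify and define the first run, so μ_max is 0.
Any realistic noise (the generator's default multiplicative sd 0.02)
breaks the degeneracy and the rule behaves as intended; the test suite
uses a lag-free logistic fixture where closed-form accuracy is checked.

**Spline μ(t).** The continuous specific growth rate is the derivative
of a cubic smoothing spline fitted to ln OD, with the penalty chosen by
generalized cross-validation (`scipy.interpolate.make_smoothing_spline`,
`lam=None`). GCV removes the one free knob a smoothing spline would
otherwise add; `lam` is exposed for override. Near a non-differentiable
corner (an exact lag hinge) the spline derivative overshoots by a few
percent — inherent to polynomial smoothing, and again absent once the
curve carries noise or is differentiable.

**Scalar metrics.** `percent_reduction(ref, x) = 100·(ref − x)/ref`;
`log10_change(a, b) = log10(b/a)` (signed, for CFU comparisons);
`titration_ion_load` converts an acid titration volume into the molar
counter-ion concentration it adds to the medium
(µL × M × ions / mL, expressed in mM).

## Differential expression

Counts are normalised to counts per million per sample (no
between-sample scaling factors; library-size CPM is the default and the
deliberate choice — compositional normalisations such as TMM are out of
scope). Per contrast, genes with zero counts in every sample are
dropped from testing and retrievable separately. On
log2(CPM + pseudocount) (pseudocount 0.5), the log2 fold change is the
difference of group means; the pooled residual variance s² (d = n₁+n₂−2
degrees of freedom) is shrunk toward a common prior by the classical
moderated-t construction: the prior (d₀, s₀²) is estimated by matching
the mean and variance of log s² to those of a log scaled
inverse-chi-square (trigamma inversion by Newton iteration); the
posterior variance is (d₀s₀² + d·s²)/(d₀+d) and the moderated t has
d₀+d degrees of freedom. If the observed spread of log s² does not
exceed its theoretical sampling noise, d₀ = ∞ (full shrinkage). If
every gene has zero residual variance the test falls back to an
unmoderated t with a warning. P-values are Benjamini–Hochberg adjusted
within the contrast, and a gene is called differentially expressed when
|log2FC| > 1 **and** FDR < 0.05, both strict, as these thresholds are
conventionally printed. Externally produced DE tables can be imported
to bypass this stage entirely.

## Trajectory and intersection algebra

Direction calls (up/down/ns) per timepoint form a gene's trajectory
vector. Named classes: `persistent_up` / `persistent_down` (the same
sign at every timepoint), `down_to_up` / `up_to_down` (opposite signs
at the first and last timepoint); every other pattern is labelled by
its literal vector (e.g. `up_ns_up`). Genes ns everywhere are excluded,
so the classes partition the DEG union. UpSet intersections are
*exclusive*: each DE gene belongs to exactly one signed membership
pattern, and pattern counts sum to the union size (property-tested).
Sets are signed by default because switcher classes require sign;
an unsigned mode collapses up/down to plain membership. Cross-regime
overlap at a shared timepoint reports co-induced, co-repressed, and the
two opposite-direction sets, which are pairwise disjoint by
construction. Genes missing from one timepoint's tested universe
(dropped zero-count genes) are treated as ns there, with a warning.

## Reporter transcription factors

The regulatory network (a CoryneRegNet-style TF→target edge list with
activation / repression / dual labels) is first cleaned: exact
duplicate rows collapse; a (TF, target) pair carrying both activation
and repression rows is removed as ambiguous unless one row is labelled
dual, in which case the dual row wins; self-loops are retained.
Low-abundance genes (mean CPM strictly below 1 across the contrast's
samples) are excluded from both target sets and background, and the
background is further restricted to genes actually tested for DE.

Gene significance is s = −log10(adjusted p), with p clamped to ≥ 1e−300.
The reporter score is Z = (μ_target − μ_bg)/σ_bg, where μ_target is the
mean s over the TF's surviving targets and μ_bg, σ_bg are the mean and
*population* (divide-by-N) standard deviation over the background. The
background includes each TF's own targets (one global background, as a
single μ_bg/σ_bg implies); a leave-one-regulon-out background is
available behind a flag, as is the sample-sd formula. As written, Z
carries no √k size correction, so its null spread scales as 1/√k — a
property the tests assert. Size-aware significance therefore comes from
a sampling null: the mean s of random same-size gene sets drawn from
the background without replacement, p = (1 + #{null mean ≥ μ_target}) /
(n_draws + 1), one-sided for enrichment, BH-adjusted across scored TFs.
TFs with fewer than `min_targets` (default 3) surviving targets are
listed unscored with the reason. Dual-effect targets enter Z and the
direction profiles as ordinary targets; profiles report the fractions
of targets called up / down / ns.

## Synthetic data generator

The generator emulates the study design at desk scale so recovery can
be measured against known truth; it is not a read-level simulator.

- **Counts.** Negative binomial with mean m and dispersion φ
  (variance m + φm²); φ is gamma-distributed per gene with mean 0.1
  (shape 2), and φ = 0 degenerates to Poisson. Baseline relative
  expression is log-normal (location 4, scale 1.5). Library sizes are
  drawn once per sample, uniform in 1–2 million — a deliberate ~10×
  rescaling of the study's 11.4–17.3 million read pairs that preserves
  the relative depth spread while keeping simulations fast; the range
  is configurable.
- **Effects.** Per contrast, exactly `round(de_fraction·n_genes)` genes
  (default fraction 0.1) receive a true log2FC with |log2FC| uniform in
  [1.5, 4], applied to stress samples only. Signs are assigned so that
  up- and down-regulated transcript *mass* approximately cancels
  (greedy balancing in random visiting order): within each sample the
  expected counts are renormalised to the drawn library size, as in a
  real sequencing run of fixed depth, and mass balancing prevents that
  closure from imposing a spurious fold-change on unaffected genes.
  Real datasets are not guaranteed to be mass-balanced; strongly
  asymmetric regulation would require a compositional normalisation
  that is deliberately out of scope here.
- **Replicates.** Default 3, mirroring the biological triplicate used
  for the growth experiments; the transcriptome replicate count is not
  something the generator can know, so it is a default, not a claim.
- **Network.** One planted-active TF (configurable) whose regulon
  (default size 10) draws 80% of targets from the reference contrast's
  DE genes — edge effect matching each target's true direction — and
  the rest from non-DE genes; decoy TFs (default 20) sample their
  regulons from non-DE genes (`decoy_pool="non_de"`, the cleaner null;
  `"all"` available).
- **Growth.** Exponential (OD0·e^(μt)) or lagged logistic
  (K / (1 + ((K−OD0)/OD0)·e^(−μ(t−lag)₊))) with multiplicative
  lognormal noise, plus optional pH (linear rise to pH_max then
  decline, mimicking broth alkalinisation followed by re-acidification)
  and CFU traces.

All generators are pure functions of (config, seed).

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 800–2,000 genes,
one contrast with 3+3 replicates, 20 seeds for calibration/recovery
rates, 10 seeds for planted DE sensitivity/FDR, and 50 seeds for noisy
growth recovery — sizes at which the measured rates are stable to a
couple of percentage points between seeds while a full run finishes in
seconds. Monte-Carlo comparisons in the sampling null use a 1e−12
slack on the ≥ comparison to make ties deterministic across platforms.
BH adjustment uses a stable mergesort so equal p-values keep input
order. The trigamma inversion stops at relative step 1e−10.

## Limitations

- The DE stage is a log-CPM moderated-t workflow, not a precision-
  weighted (voom-style) fit; at very low counts its variance model is
  cruder than the mean–variance-trend approach. Importing an external
  DE table is the supported alternative.
- Library-size CPM normalisation means strong compositional shifts
  would bias fold changes; the generator avoids planting such shifts,
  and passing tests therefore say nothing about compositionally skewed
  real data.
- The reporter sampling null conditions on regulon size only; it does
  not model correlated expression within operons/regulons, so its p
  values on real bacterial data will be somewhat anti-conservative.
- Growth summaries do not fit parametric growth laws (Gompertz,
  Baranyi); lag time and carrying capacity are not estimated.
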