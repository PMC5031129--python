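# Methods

This note documents the statistical model and the algorithmic choices
behind `dropgate`: what each pipeline stage assumes, which parameters
matter and why their defaults are what they are, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The measurement model

Droplet digital PCR partitions a sample into *n* droplets of volume V
(nominally 0.85 nL). Template molecules distribute independently, so the
count per droplet is Poisson with mean λ (templates/droplet). After
endpoint PCR, a two-channel reader reports a FAM amplitude (channel 1)
and a HEX amplitude (channel 2) per droplet. Quantification reduces to
counting positives: with positive fraction p,

    λ = −ln(1 − p),   concentration = λ / V   [copies/µL].

`dropgate` targets duplex PN/PP assays: the wild-type probe fires both
dyes (double-positive, PP), the mutant probe only one (singly-positive,
PN). The channel in which *all* template-containing droplets are
positive is the assay's *positive channel* (FAM for
`fam_positive_pnpp`); the other, where PN and PP separate, is the
*variable channel*. The mutant allele frequency is computed from
per-allele occupancies,

    freq = 100 · λ_mut / (λ_mut + λ_wt),
    λ_mut = −ln(1 − n_PN / n),  λ_wt = −ln(1 − n_PP / n),

with n the accepted (non-outlier) droplet count. An uncorrected
count-ratio mode is provided (`poisson_correct_frequency=False`); the
two agree to <1% relative when both positive fractions are below 1%.
Note that in this assay design a droplet co-occupied by mutant and
wild-type template is double-positive, so λ_mut estimated from PN
droplets alone is conservative at high loads; both gating strategies in
the field share this property since the clusters are what is observable.

## Pipeline stages and parameters

The plate is the unit of state: droplet table, per-well metadata,
resolved parameters, and a step cursor. Assay types form a
single-inheritance registry rooted at `generic` (QC + empty removal
only); `pnpp` adds the gating steps, and `fam_positive_pnpp` /
`hex_positive_pnpp` fix the positive channel. Resolution walks the
ancestry root→leaf, overriding steps and deep-merging parameters, so a
custom assay type can override a single number without restating the
rest.

**Failed wells.** A well fails when (a) it has fewer than
`min_total_droplets` (default 5000; a healthy run produces ≳15 000)
droplets; (b) the kernel density of the positive-channel amplitudes has
no valley, i.e. no empty/filled structure (no amplification, or a
saturated single cloud); or (c) fewer than `min_empty_fraction`
(default 0.15) of droplets fall below the first valley. The 0.15 floor
admits template loads up to λ ≈ 1.9 — beyond the assay's usable range —
while still failing saturated wells; digital quantification is anyway
unreliable when almost no partition is empty. Failure is a per-well
verdict, not an error: the well's droplets are labeled FAILED and it is
excluded from everything downstream.

**Density estimation.** Gaussian-kernel KDE with the robust Silverman
bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on
`kde_grid_points` = 512 points spanning the data range ± 3h. Peaks are
local maxima with prominence ≥ `peak_min_prominence` (default 0.02) of
the density maximum; valleys are the minimum-density grid point between
consecutive peaks. The 2% prominence floor keeps the filled peak
detectable down to λ ≈ 0.05 (where it carries ~5% of droplets and ~3%
of peak density) without admitting KDE wiggle, which is far smaller at
these sample sizes. Constant input degenerates to a single reported
peak at that value.

**Outliers.** Per channel, a Tukey-style tail fence at
Q(`outlier_top_quantile`=0.99) + `outlier_k`(=5)·IQR; a droplet
exceeding either fence is a readout outlier. The rule is parameter-light,
permutation-invariant and affine-equivariant; with zero spread nothing
strictly exceeds the fence, so degenerate wells produce no outliers.
Outliers are excluded from the Poisson denominator: they are readout
errors, not partitions.

**Empty droplets.** The cutoff is the first KDE valley of the positive
channel (both channels independently for `generic` assays, where EMPTY
requires being below the cutoff in both; a channel with no valley
imposes no constraint). Droplets exactly at a cutoff are retained on the
filled side — ties always resolve toward keeping a droplet in play.

**PN/PP gating.** The variable-channel amplitudes of the filled droplets
are fitted with a two-component univariate Gaussian mixture by EM.
Initialization is deterministic (median split; each half provides one
component's starting moments), so results are reproducible without a
random seed; the log-likelihood is asserted non-decreasing every
iteration and the loop stops at `em_tol` = 1e-6 or `em_max_iter` = 200.
Standard deviations are floored at 1e-6 of the data range to prevent
collapse. On small samples (≤ 200 points) the deterministic fit matches
a 50-restart reference fit's log-likelihood in ≥ 95% of cases (checked
against scikit-learn in the test suite).

Droplets go to their maximum-posterior component (ties to the lower
mean; lower mean = PN/mutant). Rain is then flagged by a band rule:
a droplet is RAIN if it lies more than `rain_sd_multiplier` (default 3)
*band scales* from its component's *band center* in either the variable
or the positive channel. Band centers and scales are the median and
1.4826·MAD of the component's assigned members, not the EM parameters:
the rain shelf between clusters inflates the EM standard deviations
severely (a 2% rain fraction can triple the fitted σ of a 20%-weight
component), while the robust statistics track the underlying cluster.
The positive-channel band matters because partially amplified droplets
sag below the cluster in the constitutive channel even when their
variable-channel amplitude looks ordinary.

**Minor-population significance.** A fitted minor component is trusted
as a real droplet population only if all four hold: weight ≥
`min_minor_weight` (1%), expected count ≥ `min_minor_count` (4),
band scale ≤ `max_minor_sd_ratio` (4×) the major's, and component
separation ≥ `min_separation_sds` (3) × max scale. The last two guards
reject the two characteristic failure modes of a forced two-component
fit: a diffuse "component" that is really the rain shelf, and a single
population split into two overlapping halves. Untrusted wells are
labeled single-population (all filled → PP) and deferred.

**Cross-well rescue.** Wells whose own fit was untrusted (or failed
outright) are re-gated with a consensus gate pooled from the plate's
confident wells: the `borrow_gate_quantile` (default 0.5, the median —
robust to one aberrant well) of their boundaries, band centers and band
scales. Pooling across wells is legitimate because all wells of a plate
share assay chemistry and instrument scaling. This is what makes
0.1–0.5% mutant fractions quantifiable: a 10-droplet mutant population
cannot support its own mixture fit, but thresholding at the plate
consensus recovers it. If no well is confident the plate is left
unchanged with a warning rather than guessing. Because this step reads
other wells, it is the one pipeline stage that does not commute with
subsetting.

**Manual gate.** A fixed variable-channel cutoff applied to selected
wells (below → PN, above → PP, no rain), for secondary verification of
the automated result.

**Summaries.** Per well: counts per label, concentrations for each
positive class and their total, the mutant frequency, and the gate
cutoffs used in each channel. Rain droplets count toward the Poisson
denominator (they are real partitions) but not toward either positive
class (they are unclassifiable) — a conservative choice that biases
concentrations slightly downward by the rain fraction. Failed wells
report counts only.

## Parameter editing and reproducibility

The plate records nine state components (droplet table, metadata, name,
parameters, status, cluster vocabulary, step list, dirty flag, format
version) which fully determine the analysis. Editing a parameter after
its step has run marks the plate dirty and records the earliest affected
step; the next `analyze()` rolls back exactly the labels assigned from
that step onward and re-runs, so edits never leave stale state but also
never recompute more than needed. Persistence is a zip archive of a
version manifest, the droplet table as CSV and the rest as JSON;
`restore(persist(plate))` is the identity on all nine components
(exact for floats), and a partially analyzed archive resumes to the
same result as an uninterrupted run.

## The synthetic-data generator

`simulate_well` draws k_wt ~ Poisson(λ_wt) and k_mut ~ Poisson(λ_mut)
per droplet; a droplet is EMPTY if both are zero, PP if k_wt > 0
(wild-type dominates co-occupied droplets, as its probe fires both
dyes), PN otherwise. Amplitudes are Gaussian per population; defaults
place EMPTY at (1800, 1700), PN at (8200, 2800) and PP at (8400, 8200)
with spreads 150–250 — a 21σ cluster separation in the variable
channel, echoing a clean instrument run. A `rain_fraction` (default 2%)
of template-containing droplets is repositioned along the segment from
the empty-cluster center toward their own cluster, uniformly within
50–90% of that distance: real rain consists of partially amplified
droplets between the empty/filled threshold and the positive cluster —
droplets nearer the empty cloud are physically indistinguishable from
empties and are therefore not useful ground truth. A small
`outlier_fraction` (0.05%) of filled droplets has its channel-1
amplitude scaled by 8× to emulate readout spikes. All draws derive from
a single seed; bundles are written with amplitudes fixed to four
decimals, so identical parameters produce byte-identical files.

What the generator does *not* emulate: droplet volume variability,
PCR efficiency gradients and partial-amplification kinetics (rain is
placed geometrically, not mechanistically), inter-well amplitude drift,
baseline correlation between channels, and >2-plex chemistries. Passing
tests therefore demonstrate correctness of the gating logic under the
stated population model, not robustness to every instrument artifact;
the QC thresholds in particular are deliberately overridable because
real plates vary more than simulated ones.

## Numerical and degenerate-input choices

- Saturated counts (every droplet positive) raise a saturation error
  rather than returning infinity; summaries report ∞ for a saturated
  concentration only when the well otherwise passed QC.
- A frequency with zero positives in both classes is undefined and
  reported as missing (NaN), not zero.
- Constant amplitude vectors: no outliers (nothing strictly exceeds the
  fence), a single density peak, and a degenerate-fit error from EM.
- Well ordering is row-major (A01…A12, B01…); all outputs are sorted,
  and every operation is deterministic given its inputs, so re-exports
  are byte-identical.

## Problem sizes used in the checks

The automated checks run on simulated plates sized to exercise the
statistics without waste: 200 wells of 15 000 droplets for occupancy
recovery (λ_wt ∈ [0.05, 1.0], λ_mut/λ_wt ∈ [0.001, 0.5], 2% rain);
10 well-separated wells for droplet-level gating accuracy; 50
three-well plates (including one deliberately under-filled well each)
for QC partitioning; 50 two-hundred-point samples for the EM reference
comparison; and 10 two-population samples for the exact peak/valley
oracle. These sizes give binomial standard errors well below the
tolerances being asserted.

## Known limitations

- Gating is one-dimensional per step; a joint 2-D mixture could in
  principle separate populations that overlap in both marginals.
- Only two non-empty populations are modeled; four-cluster duplex
  designs (independent targets) are out of scope.
- The mutant-frequency estimator inherits the PN/PP identifiability
  limit: mutant templates co-occupying a droplet with wild-type are
  invisible, so frequencies are compressed at high total loads.
- The consensus rescue assumes at least one confident well per plate
  and comparable amplitude scaling across wells.
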