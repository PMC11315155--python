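# Methods

## Scope and data model

aromakit covers the computational path of an HS-SPME GC–MS volatile
panel: replicate-level integrated peaks (retention time in minutes, peak
area in detector counts) → retention-index annotation →
internal-standard semi-quantification → odor-activity scoring →
multivariate group discrimination. Peak detection, spectral
deconvolution and library spectral matching are out of scope; annotation
here is by retention-index proximity only, and identification evidence
(MS / RI / pure standard) is carried as metadata.

Three containers organize the pipeline: a `PeakTable` (peaks joined to
sample metadata; one internal-standard peak per replicate), a
`ConcentrationMatrix` (wines × compounds mean/SD/replicate-count frames
with explicit `NaN` missingness — a compound not detected in a wine is
never encoded as 0), and long-format ROAV records. Chemometrics operates
on a replicates × compounds `DataFrame`; replicates enter as independent
rows and are never averaged before modeling.

## Retention index

The temperature-programmed (van den Dool–Kratz) linear form is used:
`RI = 100·(Z + (RT−RT_Z)/(RT_{Z+1}−RT_Z))` over the bracketing alkane
pair. The isothermal logarithmic variant is deliberately not provided.
Retention times outside the ladder span are extrapolated with the edge
rung pair and flagged, since ladders are user data and edge compounds may
fall outside. Annotation assigns each library entry to its nearest peak
within a tolerance (default 10 index units, a common window for
5%-phenyl columns); assignments are injective per replicate, best match
wins, and an exact tie between two library entries leaves the peak
unannotated because no spectral evidence is available to break it.
Annotation never overwrites an existing label, which makes it idempotent.

## Semi-quantification

`C = (A_analyte/A_IS)·C_IS` per replicate, with the replicate's own IS
area in the denominator (so a common detector-gain factor cancels
exactly). The reference protocol spikes 2-octanol to a final
concentration of 328.8 µg/L; both the compound and the concentration are
configurable. Replicate aggregation uses the sample SD (ddof = 1) over
the replicates in which the compound was detected; a single detected
replicate is reported with SD 0 and a low-support flag, and a compound
detected in only one of three replicates is still reported — no
replicate-consensus filter is applied. Class totals per wine sum the
detected means of each chemical class (acid / alcohol / aldehyde / ester
/ other), treating missing as 0, matching how printed "total" rows of
semi-quantitative tables are constructed.

## ROAV and key odorants

`ROAV = C/T`. The cutoff is strict: `ROAV > 1` flags a key odorant, so
`C = T` does not. Values are reported unrounded; where comparison to a
printed table is needed, half-up decimal rounding is applied at the
printed precision (`round_half_up`), while cutoff comparisons always use
the unrounded value. Compounds whose threshold is unknown ("n. f" in
reference tables) are listed in a separate unevaluable report rather
than dropped or zero-filled. Thresholds carry a medium tag
(aqueous/ethanol/unspecified); no medium correction is attempted —
thresholds are reference data taken as given.

## Packaged reference panel

The package ships a nine-wine, 128-compound semi-quantified
concentration table (means ± SD of three parallel measurements), a
39-compound odor-threshold table, the odor-activity table as printed
(numeric cells and "<1" flags), and the printed per-class totals, all
as checksummed CSVs. Two of the 45 printed class-total cells
(aldehydes/NEH and aldehydes/KJS) do not equal the sum of their own
printed summands; each summand is pinned by an independent printed
quotient, so the totals themselves are inconsistent in the source. They
are kept as printed and listed in
`PanelFixture.KNOWN_TOTAL_DISCREPANCIES`; integrity tests exclude those
two cells and check the other 43 at ±0.05 µg/L per rounded summand.

## Chemometrics

Preprocessing order: minimum/5 imputation (each missing cell gets one
fifth of its compound's minimum positive value; all-missing columns are
dropped and reported) → probabilistic-quotient normalization against a
designated reference replicate (each row divided by the median of its
elementwise quotients against the reference row) → Pareto scaling
`(x−x̄)/√s` with ddof = 1 (constant columns set to 0 and flagged). Every
transformation appends a tag to the frame's provenance list.

PLS-DA is fitted by NIPALS on the centered one-hot class matrix, with
sequential deflation of X and Y; score vectors are mutually orthogonal
by construction. Convergence is declared when the score vector changes
by less than 1e−12 relative; the iteration cap is 1000. Each component's
weight vector is sign-fixed so its largest-magnitude element is
positive. Class prediction uses the regression form `B = W(PᵀW)⁻¹Qᵀ`
with assignment by maximal predicted indicator column. The number of
components defaults to the maximizer of Q² over 1..5 (first maximizer
wins; component counts whose Y residual is exhausted are skipped).

OPLS-DA (two classes only) removes class-orthogonal components by the
orthogonal-projection construction — the part of the X loading
orthogonal to the class-covariance weight — before fitting a single
predictive component; with zero orthogonal components it reduces exactly
to one-component PLS-DA. Orthogonal scores are uncorrelated with the
class vector to machine precision.

`VIP_j = √(p·Σ_a SS_a(w_ja/‖w_a‖)²/Σ_a SS_a)` with `SS_a = (tᵀt)(qᵀq)`
the Y sum of squares explained by component a; only predictive
components contribute for OPLS-DA, and `Σ VIP² = p` always. Markers are
variables with VIP strictly above 1.

Validation: R² = 1 − RSS/TSS on the full fit; Q² = 1 − PRESS/TSS with
PRESS accumulated over stratified k-fold held-out predictions (default 5
folds, seeded, training-fold class means as the reference). The
permutation test shuffles only the labels, refits the full
cross-validation per permutation, and reports
`p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + B)`, so `p ≥ 1/(B+1)`. A drawn
permutation identical to the observed labeling is redrawn: the observed
labeling is exactly what the estimator's +1 already counts, and at small
n duplicates are otherwise frequent (at n = 9 with 6/3 classes, a
100-draw run contains one in ~70% of cases).

Unsupervised views: Spearman correlations between sample rows (average
ranks on ties, via rank-then-Pearson), and PCoA by Gower double-centering
`B = −½JD²J` with eigendecomposition; axes with positive eigenvalues are
kept (scaled by √λ), negative eigenvalues — expected under
non-Euclidean metrics such as Bray-Curtis — are reported and their axes
dropped. The default PCoA metric is Bray-Curtis on imputed raw
concentrations; Euclidean and the other scipy metrics are available.
PCoA on Euclidean distances of a centered matrix equals PCA scores up to
sign.

## Synthetic panels

The generator emulates the reference study design: wines in groups,
three replicate injections per wine, IS spiked at 328.8 µg/L. Per
replicate and compound, the true concentration is log-normal around the
wine's mean with a given CV (log-normal because concentrations are
positive and printed SDs scale roughly with means); concentrations below
the LOD (default 0.5 µg/L) are absent from the peak list; the IS area is
itself log-normal (CV 5%, nominal 1e6 counts) so ratio invariance of the
quantification is actually exercised; retention times are affine in the
reference RI (0.02 min per index unit, intercept −10 min, placing RI
700–2400 in a 48-minute run) with 0.02 min Gaussian jitter, which keeps
annotation solvable at the default tolerance while nonzero. Panels are
byte-identical for identical seeds.

`fixture_spec()` mirrors the packaged panel (per-wine means from the
concentration table, CV = sd/mean per cell, 0.1 where no SD is printed).
Its reference retention indices are synthetic — the source table prints
none — spaced 12 index units apart.

The marker-recovery experiment (`two_group_spec` + `marker_recovery`)
uses the cellar-time contrast shape: a control-like group of two wines
versus a treated group of one wine, three replicates each (nine
samples), 13 markers planted at 4× fold change over 60 nulls, 25% CV.
Its preprocessing inserts a log transform between quotient normalization
and Pareto scaling: generated concentrations are log-normal, so the log
makes replicate noise homoscedastic and marker weights scale with the
planted effect rather than with baseline abundance. This choice was made
on a multi-seed sweep of standard scaling variants before freezing the
experiment; without the log step, chance correlations at nine samples
dominate the VIP tail and recovery is unstable.

What passing synthetic tests do not show: the generator draws
independent compounds (no correlation structure between co-regulated
metabolites), has no drift, carry-over, co-elution or saturation, and
its noise is purely multiplicative. Real panels violate all of these, so
recovery rates here are upper bounds on real-data performance.

## Numerical and interface choices

* Missing markers in files: empty cell or literal `NA`; never 0.
* Peak CSVs are canonicalized (sample, then retention time) before
  writing; numeric readers use round-trip float parsing so
  write→read→write is byte-stable.
* The run manifest hashes every analytic config field (output directory
  excluded) plus the seed, so numeric outputs are traceable; re-running
  an identical config and seed reproduces byte-identical CSVs.
* Exit codes of the CLI: 0 success, 2 validation/configuration failure,
  3 computation failure.
* Pipeline stage failures remove partial outputs before re-raising with
  the stage name.

## Known limitations

* Annotation ignores mass spectra entirely; compounds closer than the RI
  tolerance cannot be distinguished.
* OPLS-DA is restricted to two classes by design; multi-class problems
  go to PLS-DA.
* Q² of one-variable-dominant designs can be fragile at very small n
  when a fold isolates a class; stratification errors are raised rather
  than silently refolded.
* Thresholds are matrix-unaware: an aqueous threshold applied to a wine
  matrix shifts every ROAV of that compound by a constant factor.
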