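# Methods

This note documents the models, parameter choices, and numerical decisions
behind `szpath`, and what the synthetic validation does and does not show.

## Connectivity features

A seizure's network evolution is represented window-by-window.  Windows are
10 s long with a 1-s step (a *d*-second seizure yields `floor(d − 10) + 1`
windows; seizures shorter than one window are rejected).  Within a window,
auto- and cross-spectra are estimated by Welch's method: 2-s segments, 1-s
overlap, Hann taper, per-segment demeaning.  Band-averaged coherence sums
the complex cross-spectrum over the band's discrete frequency bins *before*
taking the squared magnitude, which keeps the estimate in [0, 1]
(Cauchy–Schwarz on band-summed spectra) and rewards a consistent phase
relationship across the band.  Band edges are half-open `[f1, f2)` on the
Welch grid so the shared edges 4, 8, 13, 30, 80 Hz are counted once; the
taper and edge conventions are explicit choices — reasonable defaults where
several are defensible.

Each band's strict upper triangle is flattened row-major and L1-normalised
to sum to 1.  Normalisation is per band block, not per whole vector: with
per-band normalisation the L1 distance between two windows is bounded by 2
per band (12 over six bands), which is what makes pair dissimilarities
above 2 representable at all.  A `mode="vector"` switch provides the
whole-vector alternative.

Preprocessing order: channel exclusion (input-driven; no automatic artifact
detection), linear interpolation of missing-data gaps at the native rate
(gaps over 50 ms reject the seizure; a per-seizure `max_gap_s` override
accommodates rare documented exceptions), polyphase resampling to the
target rate, common average reference, then zero-phase fourth-order
Butterworth bandpass (1–150 Hz) and 2-Hz-wide notches at the line frequency
and harmonics up to 150 Hz.  Gaps are interpolated *before* resampling
because the anti-alias filter would smear NaNs across the clip.

## NMF denoising and rank selection

The cohort matrix V (all seizures' windows concatenated) is factorised by
coordinate-descent NMF on the Frobenius objective from seeded random
initialisations.  Rank selection is stability-based: for each candidate
rank, 20 re-fits from different initialisations are compared pairwise by
greedily matching basis columns on cosine similarity; the rank's score is
the mean matched similarity.  Two practical points matter:

* **Converged fits are essential.**  Stability runs use `tol 1e-9`,
  `max_iter 2000`; half-converged fits differ across runs for reasons
  unrelated to rank and flatten the score curve.
* **Under-fitting ranks can be perfectly stable** (the merged solution is
  often unique), so the *largest* rank within 0.005 of the best score is
  selected — the richest decomposition that is still fully reproducible.
  Ranks above the truth split components arbitrarily and score visibly
  lower.

Identifiability caveat: exact NMF on disjoint-support bases is unique (up
to permutation/scale) only when the coefficient matrix is separable (every
component has near-pure windows).  The planted-rank fixtures construct this
explicitly; on data without pure windows the factors (not the product) are
ambiguous, which is precisely why the pipeline only ever consumes the
reconstruction V* = W·H, renormalised per band block so reconstruction
accuracy cannot leak into distances.

## Dissimilarity

DTW uses symmetric unit-weight steps (1,0), (0,1), (1,1), fixed endpoints,
no global band constraint; the pair dissimilarity is total warped L1 cost
divided by the warp-path length.  Ties in the backtrack prefer the diagonal
step.  The measure is speed-invariant (window-duplication costs nothing)
and is *not* a metric — `Diss([u], [u,v]) = ‖u−v‖₁/2` while duplicating
windows is free, which yields closed-form triangle violations — so nothing
downstream assumes the triangle inequality.  The implementation is checked
against exhaustive enumeration of all warping paths for short sequences.

Sammon projection (for visualisation) minimises the Sammon stress by
L-BFGS with an analytic gradient from a classical-MDS initialisation;
duplicate points are excluded from the stress rather than dividing by zero.
The spectrum-vs-clusters summary embeds the dissimilarity matrix by
classical MDS, clusters hierarchically (Ward), and chooses k by the gap
statistic (100 uniform-box reference sets, one-standard-error rule); k = 1
is a legitimate outcome reported as "a spectrum of pathways".

## Temporal statistics

The Mantel test permutes rows and columns of the dissimilarity matrix
jointly; Spearman's rho uses average ranks on ties.  The permutation
p-value is the literal proportion of permuted correlations at or above the
observed one (a `(b+1)/(n+1)` smoothed variant is a switch; for ≤ 7
seizures all S! relabellings can be enumerated exactly).  The implementation
is cross-checked against scikit-bio's Mantel test and calibrated under an
independence null (type-I error 0.04–0.05 at α = 0.05).  BH-FDR across
patients is delegated to statsmodels; undefined correlations (constant
matrices) are flagged and excluded.

The temporal correlation pattern scans timescales from 0.25 d up to the
largest temporal distance in 0.25-d steps.  A timescale is masked when
fewer than 7 pairs fall within it, when no new pair entered since the
previous grid point, or when either restricted vector is constant.  The
last valid timescale contains every pair, so its rho equals the global
Mantel rho bit-for-bit (both go through the same Spearman code path).

## Drift models and classification

Simulated dissimilarities combine linear (`t/7`), circadian (`sin 2πt`),
and per-seizure Gaussian noise components in quadrature with nonnegative
weights.  Because TCPs depend only on dissimilarity *ranks*, likelihoods
are invariant to overall weight scale; the search grid is therefore the
simplex `l + c + n = 1` in steps of 0.1 (66 cells, including pure noise).
Each cell is simulated 1,000 times (200 in tests and the acceptance script,
a problem-size choice); the good-match MSE threshold defaults to 0.02185.
Noise-free cells are deterministic and simulated once.

Classification applies factor-of-two dominance rules with an auditable
rationale trace: the best class must double the noise-only likelihood;
linear and circadian must be separated two-fold; a combined winner must
double both simpler models, otherwise it falls back to the single
comparable simpler model (re-checked against the noise and separation
rules) or is left other/indeterminate.  Exact likelihood ties prefer the
simpler class: a tie at the 100% ceiling carries no evidence for the extra
component.

## The synthetic generator

`synth_cohort` emulates a presurgical monitoring record: by default 16
seizures over 10 days (cohorts of this kind are recorded for roughly 2–16
days and average ~16 seizures), onset times uniform conditional on a
minimum gap (drawn exactly via the spacing transform), seizure durations
of 10–20 windows, and six-band connectivity vectors satisfying the same
invariants the real pipeline enforces.

The planted drift is a scalar latent `g(t) = l·t/7 + c·sin 2πt + n·ε`
mapped to a pathway mix λ ∈ [0, 1] by an **affine min-max squash**.  A
saturating squash (e.g. logistic) would also keep λ in [0, 1], but its
varying slope distorts the ranks of pairwise differences and a noiseless
linear cohort would no longer give exactly rho = 1; the affine map is
monotone *and* rank-exact, which is the property the ground truth must
have.  Each seizure traverses the *whole* endpoint-to-endpoint pathway at
its own rate (anchor resampling), so duration differences are pure time
dilations that DTW absorbs; the two endpoint pathways differ by a constant
per-window L1 gap, making the pair dissimilarity exactly proportional to
|λᵢ − λⱼ|.  Connectivity noise is folded (absolute value) before per-band
renormalisation to preserve nonnegativity.

Synthetic raw signals are a shared band-limited source plus independent
white noise per channel.  `snr` is defined as the *in-band* power ratio
(white noise spreads its power over the whole Nyquist range), under which
the analytic pairwise band coherence is `(snr/(1+snr))²` — 0.25 at
snr = 1, the value the estimator is calibrated against.

**Recovery conditions.**  Planted-drift recovery is validated on cohorts of
12 seizures over 7 days with sub-day spacing and noise weight 0.1.  The
combined plant uses a linear weight of 4/week against a unit circadian
weight: for both components to be identifiable inside a one-week window,
the linear drift's total range must clearly exceed the sine's pairwise
range (2), otherwise the observed pattern is statistically
indistinguishable from pure circadian.  Under these conditions the
classifier recovers the planted class in ≥ 80% of replicates; the
residual confusions are informative — pure-linear cohorts are occasionally
claimed by near-linear combined cells (l:c = 8:1) whose small circadian
term happens to match the observed noise wiggle, the same ambiguity that
leaves some real patients "other/indeterminate".

**What passing tests do not show.**  The generator plants a
one-dimensional pathway spectrum with stationary within-seizure dynamics;
real seizures can vary in ways no scalar mix captures (multifocal onsets,
multidien cycles, pathway branching), real noise is not i.i.d. across
windows, and electrode layouts differ per patient.  Synthetic validation
establishes correctness of the machinery, not clinical generality.

## Degenerate inputs and numerical conventions

Zero-variance channels, all-zero band blocks, infeasible onset-time
packings, sub-window seizures, empty grid classes, and constant distance
matrices are explicit errors (or flagged results excluded from downstream
corrections), never silent.  All randomness flows through
`numpy.random.Generator` seeded per stage via `SeedSequence` spawning;
deterministic stages are bit-identical across reruns, and every pipeline
stage records its parameters and input hashes.

## Known limitations

* The Welch taper, band-edge assignment, DTW step pattern, and the exact
  stability-NMF scoring are choices among defensible alternatives; results
  may differ in detail under other conventions.
* The published per-patient factorization deposit is required for the one
  clinical worked example; it is not redistributed with the package.
* Cross-patient dissimilarities are out of scope (electrode layouts are
  patient-specific); so are multidien cycle models and clinical-covariate
  associations.
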