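# szpath

Within-patient variability of **seizure pathways** — the trajectories that
seizures trace through the space of functional network configurations — from
multichannel ictal iEEG.

People with focal epilepsy often have seizures whose network dynamics differ
from one seizure to the next, and those differences are structured in time:
seizures closer together in time tend to follow more similar pathways, with
fluctuations on circadian (daily) and slower timescales.  `szpath` implements
the full analysis chain needed to quantify this in a single patient, plus a
synthetic-cohort generator with planted drift so that every stage can be
validated against known ground truth without any clinical recordings.

## The analysis

1. **Functional connectivity** (`szpath.connectivity`).  Each preprocessed
   seizure (1–150 Hz zero-phase Butterworth bandpass, line-noise notches,
   common average reference) is cut into 10-s windows at 1-s steps.  For each
   window, band-averaged coherence is computed for every channel pair in six
   bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–80, high-γ 80–150 Hz):

   `C_ij = |Σ_f P_ij(f)|² / (Σ_f P_ii(f) · Σ_f P_jj(f))`

   with Welch spectra (2-s segments, 1-s overlap).  Each band's upper
   triangle is L1-normalised to sum to 1, making windows comparable across
   patients and insensitive to global coherence level.

2. **NMF denoising** (`szpath.nmf`).  The cohort matrix *V* (features ×
   windows) is factorised as *V ≈ W·H* with the rank chosen by stability
   across seeded re-fits; the reconstruction *V\* = W·H* is renormalised per
   band block.

3. **Seizure dissimilarity** (`szpath.dissimilarity`).  Each pair of
   seizures is aligned by dynamic time warping (so two seizures that follow
   the same pathway at different speeds are identical) and their
   dissimilarity is the mean L1 distance over the warped path — bounded by
   2 per band, 12 in total.  Note this is deliberately *not* a metric.

4. **Temporal statistics** (`szpath.temporal`).  Spearman correlation
   between seizure dissimilarities and inter-seizure temporal distances,
   tested with a one-tailed Mantel permutation test (10,000 joint row/column
   permutations; exhaustive enumeration for ≤ 7 seizures) and BH-FDR across
   patients; plus the **temporal correlation pattern (TCP)** — the same
   correlation restricted to seizure pairs within a timescale *T*, scanned
   in 0.25-day steps.

5. **Dynamics classification** (`szpath.models`).  Seizure dissimilarities
   are simulated from the patient's own seizure times under
   `Diss(i,j) = √[(l·D_l)² + (c·D_c)² + (n·D_n)²]` where
   `D_x(i,j) = |f_x(t_i) − f_x(t_j)|`, with `f_l(t) = t/7` (slope one per
   week), `f_c(t) = sin 2πt` (period one day), and `f_n ~ N(0,1)` per
   seizure.  Each weight combination is simulated 1,000 times; a simulation
   is a *good match* if its TCP is within MSE ≤ 0.02185 of the observed one,
   and a model class's likelihood `L` is its best cell's good-match
   percentage.  A patient is classified **linear**, **circadian**,
   **linear+circadian**, or **other/indeterminate** via factor-of-two
   dominance rules (the winner must double the noise-only likelihood, linear
   and circadian must be separated two-fold, and a combined winner must
   double both simpler models).

## Worked example

Generate a synthetic 12-seizure patient with a planted *linear* pathway
drift (one pathway-unit per week, mild per-seizure noise) over a 7-day
monitoring window, then run the full pipeline:

```python
from szpath import CohortSpec, generate_cohort, run_patient

spec = CohortSpec(
    n_seizures=12, monitoring_days=7.0, n_channels=8,
    drift_params=(1.0, 0.0, 0.1),  # (linear, circadian, noise) weights
    seed=42,
)
cohort = generate_cohort(spec)
run = run_patient(cohort.seizures, cohort.times, patient_id="demo",
                  config={"nmf_rank_max": 5, "nmf_runs": 5, "model_sims": 200})
```

This prints (via `run.summary()` fields):

```
seizures analysed : 12
NMF rank          : 4
Spearman rho      : 0.789 (one-tailed Mantel p = 0.0006)
model likelihoods : L_l=30%  L_c=0%  L_lc=29%  L_n=0%
classification    : linear
```

The strong positive rho says seizures closer in time had more similar
pathways; the Mantel p-value says that association survives the matrix
permutation null; and the linear model wins the classification because its
simulations reproduce the observed temporal correlation pattern as often as
any model while the circadian and noise-only models almost never do.

The same stages are exposed as subcommands of the `szpath` CLI
(`simulate`, `fc`, `nmf`, `dissim`, `temporal`, `models`, `run-all`), reading
and writing EDF/HDF5/CSV/JSON.

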