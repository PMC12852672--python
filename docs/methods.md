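# Methods

## Model

Each audiometric subtype is a multivariate Gaussian over the six-frequency
air-conduction threshold vector (0.25, 0.5, 1, 2, 4, 8 kHz, dB HL), and a
cohort of ears is a K-component mixture p(x) = Σ πₖ 𝒩(x | μₖ, Σₖ).
Assumptions worth stating explicitly:

* **Ears are independent observations.**  Each ear contributes one row to
  the feature matrix.  This doubles the apparent sample size and ignores
  the within-patient correlation; the symmetry analysis quantifies how
  strong that correlation is rather than correcting for it.
* **Full covariance.**  Audiometric thresholds at neighbouring frequencies
  are strongly correlated, so each component carries its own unrestricted
  6×6 covariance.  The covariance-type/regularisation grid search
  (4 types × 10 regularisation values, 0.001–0.01) lets a user confirm
  this choice on their own data by mean BIC.
* **Thresholds are treated as continuous** although they live on a 5 dB
  grid.  The diagonal regularisation (0.01 dB², added to the covariance at
  every M-step) also guards against the degeneracy this discreteness can
  otherwise induce.

Fitting is expectation-maximisation as implemented by
`sklearn.mixture.GaussianMixture` with one k-means initialization per seed,
tolerance 10⁻³ on the change in mean per-sample log-likelihood, and
`max_iter` 500 (the tolerance, regularisation and covariance type are the
defaults of `GmmConfig`; `max_iter` is our choice — fits on simulated
cohorts converge within a few dozen iterations).  The per-iteration
log-likelihood trajectory is retained on every fit so EM monotonicity is
assertable; non-convergence is reported as a flag, never an exception.

## Model selection

BIC and AIC are computed on a grid of K = 2…15 × 21 seeds (294 fits; both
ranges configurable) and summarised per K by the mean over seeds with a
normal-approximation 95% CI (mean ± 1.96·sd/√n; a percentile CI would need
far more than 21 replicates to be stable).  Non-converged cells are kept in
the grid, flagged, and excluded from the summary.

The number of components is chosen by a reproducible plateau rule standing
in for the visual elbow judgement: scanning K upward, the first step whose
mean-BIC drop falls below 1% of the total drop across the grid marks the
plateau, and the K *before* that step — the last K that still improved
materially — is chosen.  A rising or flat curve yields K_min; a curve that
never flattens yields K_max.  The rule is deliberately simple and can be
overridden (`--k` / `model.k`).  The reporting seed at the chosen K is the
one with the lowest AIC, and that (K, seed) pair defines the original model
that all stability analyses perturb.

Hard labels are maximum-responsibility assignments, ties toward the lower
component index.  Cluster display order is descending cluster proportion;
mixture numbering itself carries no meaning.  Empty clusters produce
NaN-marked profiles rather than errors.

## Record cleaning

Stage order is fixed: empty-record removal → exact-duplicate removal →
same-day selection → AC–BC join → validity filter → bilateral-adult-SNHL
filter → one test per patient → ear expansion.  Decisions that were
genuinely open:

* **Same-day selection rule**: among non-duplicate curves of one
  (patient, ear, date, modality), keep the curve with the most recorded
  thresholds; break ties toward the lowest record index.  Deterministic and
  information-maximising.
* **Complete-case AC**: all six AC thresholds are required; there is no
  imputation (imputed values would enter the likelihood with spuriously
  zero error).  Partial BC curves are kept — BC is only consulted for the
  air-bone gap at 0.5/1/2 kHz.
* **Conductive loss (CHL)**: air-bone gap ≥ 25 dB at ≥ 2 of 0.5/1/2 kHz.
  AC-only tests cannot show a gap and remain SNHL candidates; the audit
  reports their count (`ac_only_tests`) so users can bound the
  misclassification this may admit.
* **Age window 18–100 inclusive**, evaluated after an optional demographic
  lookup table fills missing age/sex; patient-dates still lacking
  demographics are excluded and counted.
* **Dates compared at day resolution**; exclusion for CHL is per
  patient-date, not per patient.
* The audit records (rows in, rows out, removed) per stage; "removed" is
  negative for the final ear expansion, which doubles rows by design.

## Clinical criteria

Coles' notch: t(4k) − min(t(1k), t(2k)) ≥ 10 dB **and** t(4k) − t(8k) ≥ 10
dB.  Reading "compared to 1–2 kHz" as the better (minimum) of the two
thresholds is the stricter and more common interpretation; a mean-of-both
comparator is available (`mid_comparator="mean"`).  Reverse slope:
mean(t(0.25k), t(0.5k)) − mean(t(4k), t(8k)) ≥ 10 dB.  Both boundaries are
inclusive and both rules are exact threshold differences, hence invariant
to shifting a whole audiogram up or down.

## Symmetry

Per patient, the left- and right-ear cluster labels form a K×K contingency
table; the reported matrix is P(right = j | left = i).  Rows of unpopulated
left clusters are NaN rather than zero — a zero would fabricate a
probability.  The transposed conditioning is available by flag.

## Stability

The Jaccard coefficient |A∩B|/|A∪B| compares member-index sets of one
original cluster and one perturbed-solution cluster; each original cluster
takes the maximum over perturbed clusters (one-directional matching with
reuse, following clusterboot; an optimal one-to-one assignment mode exists
for sensitivity analysis).  jaccard(∅, ∅) is defined as 0 and flagged —
the analyses never produce it.  Three regimes:

* **Bootstrap**: resample n with replacement, refit with the original
  configuration and seed, compare over the *distinct* indices present in
  both datasets (set semantics: multiplicity affects the refit, not the
  comparison sets; the distinct fraction ≈ 1 − e⁻¹).
* **Initialization**: refit on the full data once per alternate seed, the
  original seed excluded from the pool (a 21-seed pool yields 20 refits).
* **Subsample**: for fractions 0.1…0.9, draw ⌊f·n⌋ without replacement,
  refit, compare on the subset; cluster scores are averaged within a
  replicate before averaging over replicates.

Per-cluster means carry the same normal-approximation 95% CI as the model
selection summary, computed over replicates.  Non-convergent replicate
fits, and subsample replicates smaller than K, are excluded and counted.
Default replicate counts (B = 50 bootstrap, R = 25 per fraction) are sized
for interactive use; production-scale B = R = 1000 is a configuration
change.

## Synthetic cohorts

The generator emulates the structural features the pipeline must survive,
not any real population's margins:

* Subtype means/covariances are illustrative shapes (normal hearing, two
  presbycusis-like slopes, two flat-low/sloping-high, three down-sloping of
  increasing severity, one severe notched profile).  Covariances decay as
  corr(i,j) = 0.6^|i−j| with standard deviations of 9–12 dB; `sd_scale`
  shrinks them to produce well-separated recovery benchmarks (0.3 gives
  minimum inter-mean distance ≈ 2× the within-subtype noise norm).
* Thresholds are snapped to the grid by rounding to 5 dB first, then
  clipping to [−10, 120], so boundary values remain valid.
* Paired ears share a subtype with probability `ear_correlation`
  (default 0.7), then receive independent Gaussian noise — enough
  dependence to make the symmetry analysis non-trivial without a full
  bivariate model.
* Test dates per patient are geometric with mean 2 (capped at 6); clinical
  repeat-testing patterns vary widely and this is configurable.
* SNHL tests carry BC at 0.5/1/2 kHz with an air-bone gap drawn from
  {0, 5, 10} dB, below the CHL rule; CHL tests raise AC by 30 dB in the
  speech range and set BC 30 dB better, guaranteeing the ≥25 dB-at-≥2
  criterion fires.
* Ages are truncated normal per subtype on [18, 100]; under-18
  contaminants are uniform on [5, 17]; sex is Bernoulli per subtype.

What passing tests on these cohorts does **not** show: robustness to real
EHR pathologies outside the modelled corruption set (free-text fields,
transposed ears, calibration drift), to non-Gaussian subtype shapes, or to
the heavy overlap of real audiometric phenotypes — on realistic overlap the
plateau rule merges adjacent planted subtypes, which is expected behaviour,
and bootstrap Jaccard scores drop accordingly.

## Problem sizes

Unit and property tests run at n of a few hundred to a few thousand;
recovery benchmarks use 10⁴ mixture draws with a reduced grid (K = 2…12,
5 seeds); the acceptance script uses a 3 000-patient corrupted cohort,
B = 50 bootstrap replicates and R = 25 subsample replicates.  These sizes
are chosen so the whole suite runs on a laptop in minutes while keeping
Monte-Carlo error well inside the asserted tolerances.
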