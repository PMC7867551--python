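# Methods

## Problem and scope

`sparsecoh` implements an EEG functional-connectivity biomarker analysis
for sham-controlled brain-stimulation studies recorded with a sparse
8-electrode dry cap (FP1, FP2, FPz, F3, Fz, Cz, Pz, Oz; 500 Hz;
0.5–50 Hz acquisition band). The analysis chain is:

1. re-reference referential recordings into eight nearest-neighbor
   bipolar derivations (amplitude subtraction),
2. segment into non-overlapping 2-s epochs, screen artifacts, and apply
   the usable-data inclusion rule (>120 s, i.e. sixty 2-s epochs, all
   sites present),
3. estimate Welch auto/cross spectra and band-average magnitude-squared
   coherence for all 28 site pairings in the delta (1–4 Hz), theta
   (4–8 Hz), alpha (8–13 Hz) and beta (13–30 Hz) bands,
4. classify treatment condition with an L1-regularized squared-hinge
   linear SVM over a 30-point log grid of the misclassification cost C,
5. validate with leave-two-out cross-validation, a label-permutation
   null, and out-of-sample transfer of the frozen model, and
6. correlate post-treatment coherence on the classifier's surviving
   connections with percent symptom change.

Because no public recordings exist for this kind of study, a synthetic
cohort generator with analytically known coherence is a first-class part
of the package: every estimator in the chain is tested against closed
forms derived from the generator's linear mixing model.

## Synthetic EEG model

Each session is a linear mixture of band-limited latent sources plus
white sensor noise:

    c(t) = Σ_s L[c, s] · b_s(t) + σ · ε_c(t)

`b_s` is white Gaussian noise brick-wall band-passed (zero-phase rFFT
masking) to its band with one-sided in-band density P_s (µV²/Hz). With
sinusoids this closed form would not hold; with spectrally flat sources
the in-band cross-spectral matrix is exactly

    S(f) = Σ_s P_s(f) · m_s m_sᵀ + (2σ²/fs) · I,

so any pairwise magnitude-squared coherence is known in closed form. For
one shared source with loadings a₁, a₂ and noise density N this reduces
to C = (a₁a₂P)² / ((a₁²P + N)(a₂²P + N)) — the (SNR/(1+SNR))² family for
equal loadings — which the tests use as the estimation oracle.

Default background spectrum (free parameters; the study the package
emulates does not characterize its spectra beyond band limits): one
independent source per electrode per band with densities delta 12,
theta 8, alpha 10, beta 3 µV²/Hz and sensor noise σ = 4 µV. This gives
channel SDs near 14 µV — a plausible eyes-closed resting scale — and
keeps clean epochs below the 100 µV artifact threshold.

### Planted group effects

The generator produces data in electrode (referential) space so the
bipolar-montage code path is genuinely exercised. To plant a coherence
effect between two *bipolar* sites, the coupling source's electrode
loading vector v solves B·v = u, where B is the montage's signed
incidence matrix and u the indicator of the two target sites: the source
is then exposed with coefficient 1 on exactly those two site traces and
0 on the other six. (Feasible because u is orthogonal to the montage
graph's single cycle; the solver verifies this and fails loudly for
infeasible targets.) Both default effect connections link sites with no
shared electrode, so their baseline cross-spectrum is 0 and the planted
coherence is g⁴/(2+g²)² at coupling strength g when background and
coupling densities are equal.

Defaults mirror a delta-band treatment signature: coherence *increase*
on the midline central–occipital connection (Fz-Cz ↔ Pz-Oz) and
*decrease* on the right frontal–central connection (FP2-Fz ↔ Cz-Pz),
applied only to active-arm post-treatment sessions. Baseline coupling
1.2 shifts by ±0.6 (coherence ≈ 0.17 → 0.35 and 0.17 → 0.02). These
magnitudes were chosen once to represent a large, clearly recoverable
effect; with per-participant multiplicative loading jitter (SD 0.15 on
couplings, 0.10 on background) the per-feature standardized group
separation is roughly d′ ≈ 3, so the planted contrast is nearly
separable at n = 19 vs 16. Cohort sizes default to 19 active / 16 sham
with usable duration 6.8 min, the availability pattern of the emulated
study.

Symptom percent-change scores (IDS-SR and PCL-5 analogs, positive =
improvement) are attached per participant. For active participants the
score is ρ·z + √(1−ρ²)·ε where z is the z-scored *model-implied*
post-treatment coherence on the decrease connection (computed from the
analytic CSD, not from data), with ρ = −0.68 (IDS-SR) and −0.54 (PCL-5)
— lower residual frontal coherence ↔ greater improvement. Sham scores
are uncoupled noise around a smaller mean improvement. Measured-feature
correlations attenuate below |ρ| because spectral estimation noise adds
variance the scores are not coupled to.

### What the generator does not emulate

No volume conduction or head geometry, no 1/f background, no
non-stationarity, no real artifact morphologies (ocular/muscle), no
eyes-open segments, and no participant-level treatment-response
heterogeneity beyond loading jitter. Passing tests therefore demonstrate
correctness of the estimators and the validation machinery under the
stated model — not clinical performance on real EEG.

## Spectral estimation

Welch estimation uses Hamming-windowed, mean-removed 1-s segments with
50% overlap *inside* each 2-s epoch (three segments per epoch), averaged
over all segments of all surviving epochs. Rationale: cross-epoch
averaging is what makes coherence estimable (a single segment gives
identically 1, and the code refuses n_segments < 2); 1-s segments give
1 Hz resolution, enough to cover the delta band's 1 Hz lower edge. The
density normalization matches `scipy.signal.csd` (verified bin-for-bin
in the tests); integrating the auto-spectrum recovers signal variance up
to windowing loss. Cross-spectra are averaged across epochs *before*
forming coherence; averaging per-epoch coherences would be degenerate at
one segment per epoch.

Band averages take the unweighted mean over bins whose center lies in
[low, high); bands are half-open so the shared printed edges (4, 8,
13 Hz) belong to exactly one band, with beta closing at 30 Hz inclusive.
Bins with zero auto-spectral density are treated as undefined (NaN) and
excluded from band means.

Known estimator behavior accounted for in tests: (i) under independence
the squared-coherence floor is ≈ 1/n_segments, inflated somewhat by the
50% segment overlap; (ii) band edges of a brick-wall source lose
coherence to window main-lobe leakage, so oracle tests use sources
extending ≥ 3 Hz beyond the scored band; (iii) a small positive bias
(~0.01 at ~10² segments) remains at moderate coherence, covered by the
Monte-Carlo tolerance 0.02 + 2.5·SE with SE computed at an effective
segment count of n_segments/2.

## Classifier and solver

The classifier minimizes ‖w‖₁ + C·Σᵢ max(0, 1 − yᵢ·wᵀxᵢ)². The solver is
cyclic coordinate descent in which each one-dimensional subproblem —
convex and piecewise quadratic — is minimized *exactly* by a sorted
breakpoint sweep. Consequences: monotone descent, deterministic output,
exact zeros (below C₀ = 1/(2·maxⱼ|Σᵢ yᵢxᵢⱼ|) the returned vector is
all-zero bit for bit), and convergence to the global optimum since the
nonsmooth term is coordinate-separable. Stopping: maximum coordinate
optimality violation < 1e-8 or 10,000 sweeps (estimator defaults).
Tests pin the solver to an independent L-BFGS-B solve of the smooth
split-variable reformulation (w = u − v, u,v ≥ 0) at 1e-6 relative
objective agreement, and to scikit-learn's LIBLINEAR implementation.

Conventions the analysis records because the emulated protocol leaves
them open: features are z-scored with training-fold statistics (L1
penalties are scale-sensitive; configurable off); the bias is an
appended constant-1 feature penalized like any other (configurable off);
scores of exactly 0 classify as the negative (sham/untreated) class.

For the cross-validation inner loop the same solver runs as a
warm-started ascending-C path *within each training fold* with sweeps
capped at 30 and tolerance 1e-2 scaled by max(1, C) (violations live on
the gradient scale). Accuracy curves are indistinguishable from
tight-tolerance runs in testing, at ~5× less cost. Warm starts never
cross folds: a warm start from a model that has seen the left-out
samples plus a sweep cap would leak test labels into the fold fit, which
was observed directly (null accuracies near 1) and is designed out.

## Validation protocol

*Leave-two-out CV*: each iteration draws one random sample per class as
the test set, so both conditions are always represented. Per-C accuracy
is the mean over all 2·n_iterations test predictions; best C is the
argmax with ties broken toward the smallest C (the simpler model). The
full protocol is 500 iterations over 30 C values; the desk-scale preset
uses 100.

*Permutation null*: labels are shuffled uniformly; the whole CV
(including best-C selection) is re-run per shuffle, so the null
distribution carries the same selection-maximum bias as the observed
statistic. p = (1 + k)/(1 + N) (never zero; exact validity), with the
unsmoothed k/N also reported. Full protocol: 1000 shuffles; desk-scale:
200 shuffles at 50 CV iterations each (a logged reduction — fewer
iterations per shuffle only widens the null, which is conservative).

*Refit metrics*: AUC, sensitivity and specificity come from the model
refit at the best C on all samples — in-sample by protocol, replicated
as such and documented as optimistic. AUC is the rank-based
(Mann–Whitney) area with ties counting 1/2; its 95% CI is a stratified
bootstrap (2000 resamples) of the scores, a documented choice since the
emulated protocol does not state its CI method. Degenerate score sets
(all equal) report AUC 0.5 with a warning.

*Transfer*: the frozen model — weights plus the frozen training
standardization — is applied to pretreatment sessions without
retraining; since none of those sessions carries the treatment effect, a
sound model should assign the majority to the sham/untreated side.

Pre-vs-post contrasts treat recordings as exchangeable units (the
emulated protocol's choice, replicated); no nested CV is added around
the C selection, and no multiple-comparison correction is applied across
the four contrasts or instruments — raw p-values are reported.

## Association analysis

Nonzero-weight connections are grouped by weight sign into an
"increase" and a "decrease" set; per-set coherence is the mean over
member pairs (single-pair sets pass through). Values are z-scored across
participants (n−1 denominator) and tested against each instrument's
percent change with Pearson's r (the linear-coupling design) and a
two-sided p from the t distribution with n−2 df; Spearman is available
by flag. The analysis band is an explicit parameter.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the acceptance script
(chosen as the package's own fast-iteration preset): planted-effect
recovery at n = 19 + 16 post sessions with 100 CV iterations × 200
permutations; null calibration over 100 independent 6 + 6 post-only
cohorts of 128 s sessions with 10 CV iterations and 19 permutations
(at N = 19 the achievable p-grid makes "reject at α = 0.05" exactly the
k = 0 event, so the nominal level is exact by symmetry); coherence
oracle at 3 SNRs × 3 durations (90–900 Welch segments). Seeds fan out
from a single master seed through `SeedSequence` spawn keys; every
derived seed stays below 2³¹.

Degenerate inputs: montages naming absent electrodes, single-class
training sets, single-segment spectra, zero-variance z-scores, < 4
correlation pairs, and missing cohort cells all raise typed errors
naming the offending entity.

## Known limitations

- The exact nearest-neighbor bipolar pair list of the emulated study is
  not public; the default montage is a geometric nearest-neighbor
  choice on the 10–20 layout and is fully configurable via a two-column
  montage file, which is the source of truth.
- Artifact screening is a deterministic amplitude/drift proxy (100 µV
  peak, 100 µV within-epoch trend range) for what was originally manual
  visual inspection.
- EDF is supported on the read side (via mne, honoring physical
  dimensions); sessions are written as delimited text.
- In-sample AUC and same-CV C selection are optimistic by construction;
  they are replicated as protocol, not endorsed as unbiased estimates.
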