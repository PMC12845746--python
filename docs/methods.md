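# Methods

## Signal model and preprocessing

A raw sEMG channel is modelled (and simulated) as a band-limited stochastic
carrier whose local RMS amplitude tracks muscle activation. The
preprocessing chain — zero-phase Butterworth band-pass 20–400 Hz (design
order 4), full-wave rectification, zero-phase 20 Hz low-pass (design order
4) — is an amplitude demodulator: it recovers the activation envelope up to
a constant factor (the rectified mean of a unit-RMS Gaussian carrier,
√(2/π) ≈ 0.80). Zero-phase (forward–backward) filtering is used throughout
so that burst-timing metrics are not biased by filter group delay;
"4th order" refers to the design order of the underlying low-/band-pass
prototype. Envelopes are clipped at zero because zero-phase filtering can
ring slightly negative at sharp onsets and the factorisation requires
nonnegative input.

MVC normalisation uses, per muscle, the maximum over calibration trials of
the maximal 1 s sliding-window RMS of the band-passed signal. The "stable
window" requirement is operationalised as the RMS-maximising window: it is
deterministic and needs no manual stability judgment. Note the denominator
is a windowed RMS while the dynamic trace is a linear envelope; the ≈0.80
demodulation factor therefore survives into the normalised cycles. This is
a fixed multiplicative constant per muscle and cancels in weights (unit
normalisation), correlations and ANOVA contrasts.

One representative cycle — the median-duration cycle, lower median, ties to
the earlier one — enters analysis per subject × timepoint. Cycles are
half-open, 0-based sample ranges; normalised-cycle time maps index i to
i/99. Phase boundaries are rescaled proportionally and rounded to the
nearest interior index.

## Time-domain metrics

iEMG includes the Δt = 1/fs factor so its unit is µV·s (a sample-sum mode
is switchable); RMS is √(mean of squares). Both are computed on rectified
band-passed signals at the original sampling rate — not on MVC-normalised,
time-normalised envelopes — because these metrics are reported in absolute
microvolt units. Per-phase windows partition the cycle, so per-phase iEMG
sums exactly to the cycle iEMG.

## Synergy factorisation

The envelope matrix D (muscles × 100) is factored as D ≈ WC with W, C ≥ 0
by Lee–Seung multiplicative updates on the Frobenius objective, with a
denominator guard of 1e−12. Initial entries are i.i.d. uniform on
(0, max D] (exact zeros excluded — they are absorbing states of
multiplicative updates). Each restart runs to convergence (VAF change
< 1e−6 over a 10-iteration window, max 1000 iterations); the best of 20
restarts by VAF wins. VAF = 1 − SSE/SST with uncentred SST = Σ D² (the
global-VAF convention of the synergy literature; a centred variant is
config-selectable). Stopping a run the moment VAF crosses the selection
threshold is deliberately not done: it would make the reported VAF an
artifact of iteration scheduling.

Model order is the smallest k with VAF > 0.90, swept upward from 1. The
sweep range is configurable up to 14 but is capped at the number of muscles
(10 by default): orders beyond the matrix's smaller dimension are
degenerate. If no order reaches the threshold, the best-VAF factorisation
is returned flagged as a non-convergent selection. Weight columns are
re-normalised to unit Euclidean norm with compensating row scaling of C, so
weights are comparable across subjects.

## Reference clustering and matching

Weight vectors from the control group's pre-intervention sessions are
pooled and clustered by K-means (squared Euclidean), best of N random
(Forgy) initialisations; empty clusters are re-seeded with the worst-fit
point of a multi-member cluster. The data clustering uses N = 1000 repeats
by default. The cluster count is chosen by the Gap statistic with reference
sets drawn uniformly on the per-dimension bounding box of the data,
B = 100 draws, sd(k) scaled by √(1 + 1/B), taking the smallest k with
Gap(k) ≥ Gap(k+1) − sd(k+1). Reference-set clusterings use fewer restarts
(10 by default): the null dispersion estimate is an average over B draws
and does not benefit from the same polish as the single data clustering.
Centroids are clipped to nonnegative, re-normalised to unit norm, and
ordered by their peak-weight muscle for determinism.

Matching is greedy one-to-one: repeatedly take the highest remaining
(synergy, reference) Pearson correlation that clears the 0.6 threshold,
ties to the lower reference index. One-to-one (rather than many-to-one)
assignment is a documented choice; leftovers count as unmatched in the
census. The census conserves counts by construction: per-reference
occurrences plus unmatched equal the total synergies submitted.

## Activation timing

Duration is the fraction of the 100 cycle points at or above 20% of the
profile's maximum (a common burst-detection convention; configurable); peak
time is the argmax (earliest on ties) mapped to [0, 1]; onset is the start
of the longest contiguous supra-threshold run with the cycle treated as
circular, because kick bursts routinely span the cycle wrap. All three are
scale-invariant and shift-equivariant, which the property tests exercise.

## Mixed 2 × 2 ANOVA

Between factor group, within factor time. Sums of squares: group is tested
against subjects-within-group; time and group × time against the
time × subject residual. With two within-subject levels sphericity holds
trivially, so no correction is applied. p-values come from the F survival
function (regularised incomplete beta, via scipy). ηp² =
SS_effect/(SS_effect + SS_error-of-that-effect), banded small/medium/large
at 0.01/0.06/0.14 (closed on the left). Simple effects are paired t-tests
(pre vs post within each group) and independent t-tests (groups within each
timepoint), Bonferroni-multiplied by the family size (2) and capped at 1.
The outcome runner applies the same model to every column — iEMG/RMS per
phase × muscle, matched-synergy weights per muscle, timing parameters per
synergy, synergy count — without correction across outcomes, and drops
subjects that lack a complete pre/post pair for an outcome (e.g. an
unmatched synergy at one session), recording the n actually used.

## Synthetic-study generator

The generator emulates the acquisition design the analysis assumes:
10-muscle montage at 2000 Hz, two groups of 15 subjects, pre/post sessions,
kick cycles of 0.6 s (two cycles per trial with 0.25 s silent pads), phase
boundaries at 40%/80% of the cycle, and three MVC trials of 2 s per muscle
at relative efforts 0.90/1.00/0.95.

Ground truth: each of 3 synergies has 2–4 dominant muscles (disjoint
partition of a random permutation; dominant weights U(0.5, 0.9), others
U(0.05, 0.2) — physiological crosstalk level) with unit-norm columns, and a
circular Gaussian burst (SD U(0.05, 0.09) of the cycle) at a distinct
centre; with three synergies the centres sit near 0.65, 0.90 and 0.12 of
the cycle (plantar-flexor, postural and propulsion-like placement). Burst
widths are chosen narrow enough that the generating order is identifiable:
with broad, heavily overlapping bursts a rank-2 factorisation can exceed
90% uncentred VAF and the order-selection rule would legitimately return 2.

Individual variability: per-subject and per-session additive Gaussian
jitter on weight vectors (SD 0.06 and 0.03, re-normalised; session-level
burst jitter at 0.75× the subject-level SDs of 0.02 cycle on centres and
lognormal σ 0.10 on widths), a subject activation scale U(0.4, 0.8) MVC,
per-muscle MVC gains U(200, 600) µV, and additive envelope noise
SD 0.02 MVC-units. Session weight variability reflects the high
test–retest reliability reported for synergy weights. Raw signals are the
time-stretched envelopes modulating unit-RMS 20–400 Hz Gaussian carriers.

Intervention effects (experimental group, post session only):
multiplicative. The burst width of the postural-like synergy shrinks by
×0.6, and the weights of the propulsion-like synergy's two prime movers are
multiplied by 3.0 before the column is re-normalised. The multiplier needs
a comment: because columns are unit-norm, the induced change of the
normalised weight *share* saturates near +0.13 no matter how large the raw
multiplier is; ×3.0 produces a share change of ≈ +0.11. Re-expressing
published post-intervention weight tables of this study type on unit-norm
columns gives share changes of ≈ +0.07 to +0.10 — effects that, at n = 15
per group, sit exactly at the edge of significance (which is also where the
published interaction p-values sit, 0.03–0.04). The default is set slightly
above that regime so the end-to-end directional validation detects the
injected effects reliably rather than coin-flipping; it is a power choice,
config-exposed, and the published-magnitude regime is reproducible by
setting the multiplier to ≈ 2.

What the generator does *not* emulate: electromechanical delay, fatigue
drift within a trial, electrode lift-off/motion artifacts, inter-muscle
crosstalk correlation in the carriers (carriers are independent), bimodal
burst shapes, and non-stationary cycle durations within a trial. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated statistical model, not robustness to every artifact of real
underwater recordings.

## Numerical and reproducibility choices

All randomness derives from one root seed through named, CRC-tagged seed
sequences (per stage, per subject × timepoint, per restart), so identical
configurations reproduce byte-identical artifacts; stage manifests record
input digests, parameters and seeds. Degenerate cases are defined
explicitly: all-zero data has undefined VAF (error); identically-zero
activations have no timing (error); an all-identical point set selects one
cluster; a zero-variance error stratum yields F = 0 when the effect SS is
also zero. Ties break deterministically everywhere (earliest index, lower
reference index, lower median).

Problem sizes in the shipped tests and acceptance script are scaled to
desk hardware: clustering uses 150–300 K-means repeats and Gap B = 30–50
(the package defaults remain 1000/100), order-recovery uses 25–50
replicates, and the null-calibration uses 500–2000 simulated tables.

## Known limitations

- The Gap statistic with a raw bounding-box reference can over-split
  strongly anisotropic weight clouds; on NMF-estimated weights it
  occasionally returns 4 clusters for a 3-synergy truth. Matching still
  functions (the extra centroid splits one cluster), but census counts then
  spread over more references. A PCA-rotated reference box is out of scope.
- One-to-one greedy matching is order-independent but not globally optimal;
  with the 0.6 threshold and well-separated centroids the difference has
  not been observed to matter.
- The ANOVA runner tests every outcome without cross-outcome multiplicity
  control, mirroring the analysis style it reimplements; interpret
  single-outcome significance accordingly.
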