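# Methods

`megpac_rsn` implements a resting-state-network (RSN) analysis for
source-space MEG built on phase-amplitude coupling (PAC), together with the
jackknife group statistics used to compare RSNs across four recording
conditions (medication OFF/ON at each of two recording sessions), and a
synthetic source-space generator with planted ground truth that makes the
whole chain testable end to end. This note documents the model, the numerical
choices, and what the synthetic validation does and does not show.

## The analysis chain

### Maximum phase-amplitude coupling

For each source (vertex) the direct PAC estimator is evaluated on a grid of
candidate pairs, phase frequency f_phi ∈ [2, 30] Hz (1 Hz steps by default)
× amplitude frequency f_a ∈ [80, 150] Hz (5 Hz steps):

    PAC = N^(-1/2) · |Σ_t a(t) e^{i φ(t)}| / sqrt(Σ_t a(t)²)

where φ(t) is the analytic phase of the f_phi-band component and a(t) the
analytic amplitude of the f_a-band component. By Cauchy–Schwarz, PAC ∈ [0, 1];
it is invariant to signal scaling and (because the DC bin is zeroed) to
constant offsets. The per-vertex maximizing pair (f̂_phi, f̂_a) is found by
exhaustive search; ties break toward the lowest phase then amplitude
frequency.

**Band extraction.** Bands are extracted in the frequency domain: the FFT of
the signal is multiplied by a one-sided Gaussian window (negative frequencies
zeroed, positive doubled), giving the zero-phase analytic band signal
directly, as with Morlet-wavelet filtering. The window's σ is a quarter of
the nominal bandwidth (band edges at 2σ). Gaussian windows matter for the
grid search: with flat passbands, every band containing a narrowband
oscillation returns the same analytic phase, so the comodulogram has a
plateau and the argmax is decided by noise; a window peaked at the band
centre maximizes the in-band SNR at the true frequency and makes the argmax
well defined. Half-bandwidths: max(1 Hz, f_phi/4) for phase bands;
max(phase grid) + 5 Hz for amplitude bands, so the modulation sidebands
f_a ± f_phi pass for every phase frequency on the grid.

**Computation.** Band signals are spectrally narrow, so they are evaluated
on a reduced time grid (≥ 200 Hz) by folding the masked spectrum modulo the
reduced length — an exact decimation up to the truncated Gaussian tails
(relative error ~3·10⁻⁶). The phase × amplitude reduction then runs as
batched BLAS matrix products in float32. An amplitude band whose envelope is
below 10⁻⁹ of the total signal scale is treated as empty (PAC = 0), so
constant inputs do not produce arbitrary ratios of rounding noise.

### megPAC synthesis

For each vertex, the local maxima and minima of its f̂_phi-band component are
detected (strictly alternating by construction; between two same-type extrema
the more extreme one is kept). The f̂_a-band analytic amplitude is sampled at
those times, signed + at maxima and − at minima, linearly interpolated
between samples (constant extension at the edges), low-passed, and sampled on
a uniform 10 Hz grid.

The anti-alias low-pass (zero-phase 4th-order Butterworth at 0.8× the output
Nyquist, i.e. 4 Hz for the 10 Hz output) is essential, not cosmetic: the
extrema-sampled series carries strong content at f̂_phi and its harmonics,
which for f̂_phi > 5 Hz would alias into the 10 Hz series. The aliased
component has a random per-vertex phase, so without the filter it buries the
slow co-fluctuations the group stage needs (in the synthetic validation,
network recovery degrades from phi = 1.0 to phi ≈ 0.4). A polyphase
resampler, as used by standard MEG toolboxes for the same step, applies the
equivalent filter implicitly.

The signed-extrema convention (+ at maxima, − at minima) is the default and
is switchable (`signed_extrema`); with gamma amplitude gated by low-frequency
phase, the maxima carry the modulated amplitude and the minima the floor, so
the signed, interpolated, low-passed series tracks the slow modulation
envelope.

### Network extraction

Per-subject megPAC series are smoothed on the cortical mesh with a Gaussian
kernel of 7 mm FWHM over Euclidean inter-vertex distances. The kernel is
balanced into a doubly stochastic operator by symmetric Sinkhorn scaling
(tolerance 10⁻¹²): rows sum to 1, so spatially constant maps are unchanged,
and columns sum to 1, so the global mean of every time sample is preserved.
On a regular grid the balanced kernel stays Gaussian up to boundary effects.

Each vertex series is z-scored per subject (zero-variance vertices map to
zeros) and subjects are concatenated along time, so every subject contributes
unit variance to the group correlation. The Pearson correlation matrix over
an evenly distributed vertex subset (deterministic farthest-point sampling;
default size min(n_vertices, 1000)) is decomposed by SVD, and the first ten
modes are kept. Full-resolution coupling-strength maps come from correlating
every vertex's series with each subset mode's time course and rescaling
|r| / max|r| into [0, 1], which makes the 40 %-of-maximum thresholds used
downstream well defined. Mode signs are fixed (largest-magnitude component
positive) for reproducibility; maps are sign-invariant by construction.

The SVD is taken of the correlation matrix (not of the reduced time-series
matrix); the two have the same mode subspace and differ only in the scaling
of the singular values.

### Jackknife statistics

For each condition with N usable subjects, the group stage is re-run N times
leaving one subject out. Per-subject PAC search, megPAC synthesis and
smoothing do not depend on the rest of the group, so they are computed once
and reused — exactly equivalent to re-running the full chain per run.

Templates: the full-cohort (no-leave-out) RSNs of each condition are matched
to the named reference networks; each jackknife run's ten modes are then
matched to the condition's templates by the phi coefficient of the maps
binarized at 40 % of their maximum. Within a run, templates are assigned to
*distinct* modes greedily by descending phi: the analysed networks are
different RSNs by construction, and without exclusivity two templates can
claim the same mode when their phi values are close, which injects large
spurious condition differences. A run whose best phi is ≤ 0 for some
template is excluded from that template's statistics (logged).

**Variance correction.** Leave-one-out estimates vary about (N−1) times less
than independent subject-level estimates. With `jackknife_correction` on
(default), within-cell deviations of the run-level values are inflated by
(N_c − 1) per condition cell before any test, which restores subject-level
sampling variance (t/(N−1), F/(N−1)² in the balanced case). Without it,
run-level tests are wildly anticonservative, because different conditions
have different subject cohorts and therefore differ at subject-sampling
scale while within-cell spread is at leave-one-out scale. The switch exists
because published run-level degrees of freedom suggest uncorrected tests are
also in use; both modes are tested. The correction assumes the run statistic
is smooth in the left-out subject; for median-type statistics over few
quantized values the jackknife variance estimate is unreliable (see
limitations).

Per vertex (included if it reaches 40 % of the template maximum in at least
one condition), coupling strengths are compared with a two-way ANOVA
(medication × session, Type II sums of squares for the unbalanced cohorts,
implemented with vectorized QR projections and verified against statsmodels),
followed by Welch two-tailed t-tests on the four contrasts of interest
(OFF vs ON within each session, first vs second within each medication
state). All tests are unpaired: the cohorts exclude different subjects, so
paired tests are not possible. One Benjamini–Hochberg FDR family spans
vertices × networks × contrasts.

Overlap with external (healthy-control) templates: per run, the phi
coefficient between the matched map and the control template (both binarized
at 40 %); pairwise Welch tests between the four conditions (Student
statistics reported alongside), Bonferroni-corrected over the 6 condition
pairs × number of networks. Summary means ± sd are reported on the raw phi
values; tests run on the variance-corrected values.

Low-frequency component: per run, the vertex-wise best phase frequency is
the *mean* over the run's subjects (a mean, not a median, so the run-level
value varies continuously under leave-one-out), and the run's value per
network is the *median* over the network's 40 %-mask vertices. A three-way
ANOVA (network × medication × session, all interactions, Type II via
statsmodels) with partial eta squared η²p = SS_effect/(SS_effect + SS_error)
and Bonferroni-corrected pairwise post-hoc tests for significant factors.
Degenerate fits (zero residual variance from quantized medians) are mapped
to F = 0, p = 1 when the effect SS is also zero.

## The synthetic generator

Per-vertex signal model (sampling rate 600 Hz, 120 s by default):

    x(t) = sin(2π f_phi t + θ_v)
         + κ_eff · m_net(t) · g(t) · sin(2π f_a t + ψ_v) + ε(t)

- `g(t) = (1 + sin(2π f_phi t + θ_v))/2` gates gamma amplitude so it peaks
  at the *maxima* of the slow component — the property the signed extrema
  sampling exploits (a gate in quadrature with the slow oscillation would
  yield high PAC but an uninformative megPAC series).
- `m_net(t)`: slow positive envelope shared by all vertices of a network
  within one recording — the logistic of standardized low-pass-filtered
  white noise (cutoff 0.5 Hz, chosen to survive the 10 Hz megPAC resampling
  and to mimic haemodynamic-scale fluctuation). This shared envelope is what
  makes megPAC series co-fluctuate within a network.
- θ_v, ψ_v: uniform random per vertex, so oscillatory phase carries no
  network information.
- κ_eff = κ × condition multiplier; κ = 0.9 by default. Background vertices
  have κ = 0 and a random slow frequency in [2, 30] Hz.
- ε: white Gaussian noise, sd 0.5 — placing the planted maximum PAC near
  0.2, the order of strong empirical PAC values.

Three planted networks sit on disjoint patches around farthest-point-sampled
seeds with sizes n/5, n/7 and n/9 (distinct sizes keep the blocks'
correlation-matrix eigenvalues apart; equal-size, equal-strength blocks have
a degenerate leading eigenspace whose SVD modes mix the blocks, making
recovery ill-posed for any method). Planted pairs: (12, 90), (8, 110),
(5, 130) Hz.

The default planted condition effect multiplies coupling by 1.5 in half of
the first network for the second-session conditions. That subregion's
*baseline* coupling is scaled to 0.45 (half the core's 0.9): the
coupling-strength maps are normalized to their maximum, so a boost inside
the map's own maximum region would be absorbed by the rescaling (and
reappear as apparent suppression elsewhere in the network) instead of being
visible at the planted vertices. Keeping the boosted region below the
network core anchors the normalization in unaffected vertices.

Cohorts: a pool of 20 subjects; each condition drops a distinct random
subset, giving usable group sizes 18/18/17/19 — so condition comparisons are
unpaired by construction. All randomness derives from one master seed;
sub-seeds are deterministic per (subject, condition).

**What the generator does not emulate.** Sensor-space acquisition, artifact
structure, head geometry and source leakage, 1/f background spectra,
between-subject anatomical variability, within-network frequency
heterogeneity, and clinical covariates. Passing tests show the pipeline
recovers what was planted under this model and controls its error rates at
these sample sizes; they are not evidence about effect sizes in real MEG.

## Validation experiment sizes

The replicate-heavy statistical experiments run on an 80-vertex grid surface
(planted networks of 16/12/9 vertices), 20 s recordings at 500 Hz, a coarse
2 Hz / 10 Hz search grid, and the full 18/18/17/19 cohorts; the recovery
experiments run at full default parameters (single-vertex frequency recovery:
60 s; network recovery: 300 vertices, 8 subjects, 120 s at 600 Hz, default
grid). The low-frequency experiment uses the 300-vertex surface because its
run statistic is a median over network vertices and needs enough vertices to
vary smoothly under leave-one-out resampling.

## Known limitations

- The jackknife variance correction is exact for linear statistics and a
  good approximation for smooth ones; for the median-based low-frequency
  statistic over few vertices it can misestimate variance badly (medians of
  quantized grid frequencies can have exactly zero leave-one-out spread).
  The pipeline mitigates this by using across-subject means at the vertex
  level and enough vertices per network, but small networks remain fragile.
- Coupling-strength maps are normalized per map; only relative spatial
  statements are meaningful, and a global coupling change between conditions
  is invisible by design.
- Template matching is threshold-based (phi at 40 %); near-degenerate mode
  pairs can swap between jackknife runs, which the exclusive assignment
  reduces but cannot eliminate.
- Euclidean distances stand in for geodesic ones in smoothing and
  subsetting; at 7 mm FWHM on the meshes used the difference is negligible,
  but for highly folded surfaces geodesic distances would be preferable.
- The maximum-PAC search runs per recording; whether a subject's search
  should be shared across conditions is a design choice (per-recording keeps
  conditions independent and is the default).
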