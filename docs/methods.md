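# Methods

This note documents the models, estimators, parameter choices and numerical
conventions of `pacwm`, and what the synthetic-data generator does and does
not emulate.

## Data model and conventions

A *session* couples a trial table (loads 1/3, encoded categories 1–5,
correctness, reaction time, event times on a session clock), per-channel LFP
epochs and per-unit spike trains. All times are seconds; trial-relative time
0 is maintenance-period onset; sample windows are half-open `[start, end)`.
Epochs span [−0.5, 3.0) s so that every filtering step has ≥0.5 s of padding,
and all statistics are computed on the trimmed [0, 2.5) s maintenance window
(1,000 samples at 400 Hz), which removes filter edge artifacts. Phases are
radians in (−π, π] with 0 at the oscillation peak (cosine convention). Every
stochastic operation takes an explicit numpy `Generator`; output artifacts
record the seed.

## LFP preprocessing

Action-potential transients are removed from the raw trace by linear
interpolation over [−1, +2] ms around each spike onset (overlapping windows
merged, edge windows clamped), using the spikes of all wires of a bundle.
The trace is then zero-phase low-pass filtered at 175 Hz (Hamming-windowed
sinc, transition width min(max(0.25·f_edge, 2 Hz), f_edge), applied
forward–backward), polyphase-resampled to exactly 400 Hz from any source
rate, and line noise is removed with zero-phase FIR band-stops at
59.5–60.5 Hz and 119.5–120.5 Hz. The 1-Hz-wide notches use twice the usual
tap count; a several-second filter is the price of a notch that actually
reaches depth at 60 Hz, and it is applied to continuous recordings, not
epochs.

Trial rejection is deterministic: amplitudes are z-scored over all samples
of all trials of a channel, capped at |6| SD, re-z-scored, and a trial is
rejected if any |z| > 4; separately, lag-4 sample differences (10 ms at
400 Hz) of the capped signal are z-scored and a trial is rejected if any
|z| > 10. The z-scores pool all samples of all trials per channel; per-sample
variants were considered and rejected to keep the rule invariant to
within-trial nonstationarity of the variance estimate. A zero-variance
channel retains all trials and flags the degeneracy. A JSON report records
which rules fired. The manual-inspection step used with patient data is
deliberately replaced by these reproducible rules.

## Spectral estimation

Band-limited phase/amplitude comes from zero-phase FIR band-pass plus
Hilbert transform per trial. The wavelet bank holds 40 complex Morlet
kernels, 2–150 Hz log-spaced, with 3–10 cycles also log-spaced, each
normalized to unit energy so amplitudes are comparable across frequencies
before z-scoring (the normalization is recorded here because alternatives —
unit peak, unit L1 — change absolute amplitudes but none of the z-scored
statistics). Convolution uses reflection padding; a reconstruction quality
control regresses the band-limited original on the band-limited sum of all
wavelet-filtered signals in sliding 500-ms windows (25-ms step) and reports
R² per frequency × window.

## PAC estimation

The modulation index uses 18 phase bins over the concatenated correct-trial
maintenance windows; the comodulogram grid has phase centres 2–14 Hz in
2-Hz steps (fixed 2-Hz bandwidth) and amplitude centres 30–150 Hz in 5-Hz
steps with amplitude bandwidth equal to twice the phase centre, which keeps
the modulation side peaks inside the band. Surrogates pair the phase stream
of trial i with the amplitude stream of trial π(i) for a random
*derangement* π (no trial pairs with itself; 200 draws), and a moment-fit
normal yields z. Channel selection averages z over the theta phase centres
{4, 6 Hz} — the grid cells inside the 3–7 Hz theta band — crossed with
high-gamma (70–140 Hz) or low-gamma (30–55 Hz) amplitude centres, with
threshold z > 1.64. Trial counts are equalized across loads once per channel
by seeded subsampling before any load comparison.

Single-trial MIs are computed within each trial's 1,000-sample window and
left un-normalized: per-trial surrogate normalization is not well defined
with one trial of data, and the mixed models that consume these values
standardize them across trials anyway. Theta waveform shape is summarized
per cycle by peak–trough asymmetry (time above zero vs below zero) and
rise–decay asymmetry (trough→peak vs peak→trough duration); cycles are
delimited by zero crossings of the 3–7 Hz signal and trials need ≥3 cycles.
Nesting detection averages 500-ms raw-signal windows centred on the
gamma-amplitude maximum within each occurrence of the preferred theta-phase
bin and calls the channel nested when ≥3 local maxima (prominence ≥2 % of
the waveform range, to ignore residual averaging noise) fall within 45 ms
of the window centre.

## Spike-field coherence

Each spike takes the wavelet phase of its nearest LFP sample. Raw MVLs are
computed on spike sets subsampled to the smallest condition's count
(≥50 spikes per condition, ≥10 for the preferred/non-preferred contrast in
category cells; 500 subsample repetitions at full scale, fewer in tests) and
z-scored against surrogates that re-draw each spike's position uniformly
within its own trial's maintenance window. The uniform full-window jitter
was chosen because it destroys locking at every analyzed frequency while
preserving spike counts and trial assignment exactly; a local ±0.5 s jitter
remains available through the API. Condition contrasts are paired across
unit–channel combinations and cluster-corrected over the 40 frequencies;
cross-regional contrast families use a Bonferroni factor of 12 (two MTL
areas × three frontal areas × two cell populations). Reaction-time splits
are median splits within each load (ties to fast), averaged across loads.

## Neuron selection

Category neurons: spike counts in [0.2, 1.0) s after each picture onset are
tested with a 1×5 permutation ANOVA plus a one-sided permutation t-test of
the maximal category against the pooled remaining categories (the post hoc
contrast is read as one test against the rest; per-category post hocs are a
trivial variant). Both tests at P < 0.05 select; the per-area count is
compared with the 99th percentile of a 500-fold label-shuffle null. The
probe presentation enters only when the trial table carries a
`probe_category` column.

PAC neurons: the three-model Poisson comparison described in the README,
with two documented choices. First, spike counts per bin are modelled with a
log-occupancy *exposure offset*; without it, unequal time spent per
phase × gamma bin (inevitable when the LFP itself is coupled) masquerades as
a rate effect. The offset-free variant is available via a switch. Second,
the full-model R² that picks a selected unit's channel is the squared
correlation of observed and fitted bin counts (a deviance pseudo-R² is
available). FDR is Benjamini–Hochberg within each unit across its channel
combinations, per load. The population-level null re-runs the entire
selection after randomly re-pairing spikes with LFP trials (200 repetitions
at full scale), preserving per-trial spike counts.

The overlap of PAC and category neurons is tested against independent
subpopulations with a hypergeometric right tail.

## Noise correlations, decoding and geometry

Pairwise noise correlations are Pearson r across 101 sliding 200-ms bins
(25-ms steps covering [0, 2.5] s) within each correct trial, averaged over
trials; same-channel pairs are excluded upstream, zero-variance trials are
skipped. The null shuffles trials within condition 1,000 times. Correlation
*removal* permutes trials independently per unit within each category —
count multisets per unit and category are preserved exactly, which is
asserted as an invariant.

The greedy decoder starts from the best single unit by mean held-out
accuracy of a linear one-versus-one SVM (C = 1, fixed and logged) over
category-balanced 80/20 splits, then adds whichever unit raises accuracy
most, until the ensemble is complete; z-scoring of rates is fitted on the
training fold only (the data source does not dictate this; it avoids
leakage). Ties break to the lowest unit index. The removed-correlation
variant re-draws the within-category shuffle inside every repetition, and
greedy orders are computed per condition. Ensembles for geometry are taken
at the size where the mean accuracy curve peaks (computing them on the mean
curve rather than per repetition is the cheaper of the two readings and is
flagged as a choice). Per binary learner the signal axis is the unit normal
of the decision boundary and the noise axis is PC1 of the training responses
of the learner's two categories, mean-centred per category (an uncentred
variant exists); angles are folded to [0°, 90°] and averaged over learners
and repetitions, as are the per-category SDs of responses projected onto the
signal axis. Note that both axes are estimated from the same training
responses, so even uncorrelated noise yields folded angles above 45° — the
meaningful quantity is the intact-versus-removed difference, not the
absolute angle.

## Statistics

Paired permutation t-tests are sign-flip tests on pairwise differences;
unpaired tests permute group labels; the ANOVA permutes labels against the
F statistic. All permutation p-values use the (b+1)/(m+1) estimator, so
p ≥ 1/(n_perm+1). Cluster correction thresholds per-frequency t values at
the two-sided parametric critical value implied by the one-sided cluster
alpha of 0.025, sums t within contiguous supra-threshold runs, and compares
each cluster mass with the per-sign max-mass sign-flip null. FDR is
Benjamini–Hochberg. Mixed-effects models (trialwise PAC against reaction
time or firing rate, load as confounder, random intercepts per channel or
pair nested in patient) delegate to standard routines: REML linear mixed
models for normal responses, a variational-Bayes Poisson mixed GLM for
counts, with an overdispersion warning on misused count families.

## Synthetic sessions: what they emulate and what they do not

The generator reproduces the study conditions a desk-scale run needs: 140
trials split 70/70 across loads, five categories (load-3 trials carry three
distinct categories), 2.5-s maintenance windows inside [−0.5, 3.0) epochs at
400 Hz. LFP = pink noise with spectral exponent 1.75 (the hippocampal
log–log slope regime) + a 5-Hz theta oscillation (15 µV) + a broadband
70–140 Hz carrier (filtered white noise, not a sinusoid, so coupling spans
the band) whose envelope is A₀(1 + κ·cos(θ − φ_pref))·B(t). The lognormal
burst process B(t) (~50 ms timescale, log-SD 0.5) makes gamma amplitude
fluctuate independently of theta phase; without it the gamma-high state is a
deterministic function of phase and the three-model comparison is
unidentifiable by construction — the degenerate case the model-3 guard
exists for. Coupling depth defaults to κ = 0.6 in load 1 and 0.3 in load 3
(the load effect has this direction in the data the pipeline targets), with
a ±30 % per-trial jitter that gives single-trial PAC something to track.

Spikes are inhomogeneous Poisson by thinning at the 400-Hz LFP resolution
(per-sample probability capped at 0.9, cap occurrences counted):
λ(t) ∝ base · g_cat · exp(κ_vm cos(θ − φ₀) + (β_int cos(θ − φ_pref) +
g_γ)·1[γ high]) · G(t), normalized per trial so the mean rate stays at
base · g_cat. The explicit gamma main effect g_γ is part of the definition
of a detectable PAC neuron: on the log-rate scale a pure interaction is
absorbed by the interaction terms of the reduced model and can never pass
the two-test selection rule. The default PAC unit (base 12 Hz, β_int = 1.5,
g_γ = 0.8, κ_vm = 0.5) was calibrated once so that the injected structure
survives the measured amplitude median split (~83 % agreement with the
generative split) with ≥90 % selection power at the session's 70-trials-per-
load design; notably, *stronger* interactions reduce power for the gamma
main-effect test by concentrating high-gamma spikes at the preferred phase.
Shared trial-to-trial variability is a slow (~150 ms) lognormal excitability
process common to a unit group (σ_g = 0.35), which induces both within-trial
bin co-fluctuations — what the sliding-bin correlation statistic measures —
and trial-level gain variation. Reaction times follow
rt = 1.35 + 0.13·1[load 3] − 0.08·z(κ_trial) + ε, ε ~ N(0, 0.15²), coupling
faster responses to stronger trialwise PAC; accuracy is Bernoulli(0.94).

Not emulated: biophysics (cell types, conductances), encoding-period
dynamics beyond category-gain rates, inter-ictal artifacts, drifting
electrodes, volume conduction, and cross-regional anatomy (fixture sessions
carry one or a few channels per region label). Passing tests therefore show
that the estimators recover known structure of this generative family under
realistic measurement noise — not that patient data contain such structure.

## Problem sizes

Default analyses run at the study's scale (200 PAC surrogates, 500
SFC subsamples and surrogates, 500 decoding repetitions, 10,000
permutations). The test suite and the acceptance script use reduced but
calibration-checked sizes (60–150 surrogates, 10–50 decoding repetitions,
200–2,000 permutations) chosen so the whole suite completes in a few minutes
on one core; every reduced-size check was verified to be stable at those
sizes.

## Known limitations

NWB ingestion is a stub behind the optional `pynwb` dependency; sessions are
exchanged through the package's CSV/HDF5 fixture format. The Poisson mixed
GLM is variational (posterior SDs, hence Wald p-values, are approximate).
Absolute signal/noise angles inherit the same-data estimation bias noted
above. The jitter magnitude for SFC surrogates and the comodulogram theta
cells ({4, 6 Hz}) are documented conventions; both have config switches or
explicit parameters.
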