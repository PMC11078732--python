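# pacwm

Analysis pipeline for theta–gamma phase–amplitude coupling (PAC) and
population geometry in human working-memory electrophysiology.

During the maintenance period of a Sternberg-style task (1 or 3 pictures
from five visual categories held for ~2.5 s), hippocampal local field
potentials show coupling between theta phase (3–7 Hz) and gamma amplitude
(70–140 Hz), and some single neurons spike preferentially during particular
theta-phase × gamma-amplitude conjunctions. `pacwm` implements the full
chain needed to study this at desk scale: LFP cleaning, surrogate-normalized
PAC estimation, spike-field coherence, GLM-based "PAC neuron" selection,
noise-correlation-aware population decoding, and the signal/noise-axis
geometry that decides whether correlations limit or enhance the population
code. A synthetic-session generator with full ground truth makes every stage
testable without any data download.

It is written for electrophysiologists and computational neuroscientists who
want a reproducible, seeded, pure-Python reference for these analyses.

## Core statistics

**Modulation index.** With instantaneous phase φ(t) of the slow band and
amplitude A(t) of the fast band (Hilbert transform of the band-passed,
edge-trimmed signal), the mean amplitude per phase bin (N = 18 bins) is
normalized to a distribution p and

    MI = (log N − H(p)) / log N,   H(p) = −Σ_j p_j log p_j,

so MI = 0 for amplitude independent of phase and MI = 1 when all amplitude
mass sits in one bin. Raw MIs are z-scored against 200 trial-shuffled
surrogates (phase of trial i paired with amplitude of trial π(i), π a
derangement); a channel has significant PAC when the mean z over the
theta × gamma grid cells exceeds 1.64 (P < 0.05, right-sided).

**Spike-field coherence.** The mean vector length MVL = |⟨e^{iφ_k}⟩| over
spike phases φ_k per wavelet frequency (40 complex Morlet wavelets,
2–150 Hz, 3–10 cycles, log-spaced), with spike counts equalized across
conditions by repeated subsampling and z-scored against spike-time jitter
surrogates. For von Mises locking of concentration κ the expected MVL is
I₁(κ)/I₀(κ).

**PAC neurons.** Spike counts in 10 theta-phase bins × {low, high} gamma
amplitude (median split) are fitted by three nested Poisson GLMs
(phase as cos θ, sin θ; log-occupancy offset):

    model 1: SC ~ 1 + cos θ + sin θ + γ + (cos θ + sin θ)×γ
    model 2: SC ~ 1 + cos θ + sin θ + γ
    model 3: SC ~ 1 + cos θ + sin θ + (cos θ + sin θ)×γ

A unit is a PAC neuron when model 1 beats both reductions by
likelihood-ratio tests (P < 0.01, BH-FDR over channel combinations, either
load). The model-3 comparison rejects units that merely sit on a strongly
coupled LFP without any gamma sensitivity of their own.

**Population geometry.** Category decodability is probed by greedy forward
selection of a one-versus-one linear SVM ensemble, with noise correlations
intact or removed (independent within-category trial permutation per unit —
marginals exactly preserved). The signal axis is the unit normal of the
decision boundary, the noise axis the first principal component of
category-mean-centred responses; their angle (folded to [0°, 90°]) governs
whether shared variability is information-limiting or enhancing.

## Worked example

Generate a default synthetic session (140 trials, 70 per load, one
hippocampal channel with coupling depth κ = 0.6 in load 1 and 0.3 in
load 3, six units with known roles) and run the stages:

```
pacwm simulate --out sess --seed 4
pacwm pac      --session sess --out pac.csv  --seed 4
pacwm select   --session sess --out sel.json --seed 4
```

`pac.csv`:

```
channel,region,condition,raw_mi,z_mi,n_trials,preferred_phase,seed
hc1,hippocampus,all,0.01701...,91.095...,130,0.1745...,4
hc1,hippocampus,load1,0.03185...,60.738...,65,0.1745...,4
hc1,hippocampus,load3,0.00708...,56.335...,65,-0.1745...,4
```

The channel is strongly significant (z ≈ 91 ≫ 1.64), the preferred phase
(±0.17 rad, the bin centre nearest 0) matches the injected coupling phase 0,
and z is higher in load 1 than load 3, the injected load effect.
`sel.json` recovers exactly the three interaction-driven units as PAC
neurons and the three tuned units as category neurons, with a hypergeometric
overlap test that does not reject independent subpopulations
(`overlap_independence_p: 0.95` — the overlap unit `u_both` is both by
construction):

```
"category_neurons": ["u_both", "u_cat1", "u_cat2"],
"pac_neurons":      ["u_both", "u_pac1", "u_pac2"],
```

The geometry of information-enhancing correlations, on the two-neuron
construction (one tuned, one untuned unit, strong shared noise):

```python
from pacwm import (simulate_two_neuron_geometry, signal_noise_geometry,
                   simulate_population_rates, greedy_decoding, make_rng)

rates, labels = simulate_two_neuron_geometry(offset=2.0, noise_sd=0.5,
                                             shared_sd=3.0, rng=71)
gi = signal_noise_geometry(rates, labels, n_rep=50, rng=make_rng(1))
gr = signal_noise_geometry(rates, labels, n_rep=50, remove_corr=True,
                           rng=make_rng(1))
R, y, _ = simulate_population_rates(rng=make_rng(61))
di = greedy_decoding(R, y, n_rep=20, rng=make_rng(61))
dr = greedy_decoding(R, y, n_rep=20, remove_corr=True, rng=make_rng(61))
```

prints (via the obvious format strings):

```
angle intact 89.4 deg, removed 70.6 deg
projection SD intact 0.150, removed 0.958
max accuracy intact 0.408, removed 0.314 (chance 0.20)
```

With correlations intact the noise axis is nearly orthogonal to the signal
axis (89° of a maximal 90°), the projection of the responses onto the signal
axis is tight, and the decoder benefits; removing the correlations shrinks
the angle, inflates the projection spread and costs accuracy — the
information-enhancing regime.

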