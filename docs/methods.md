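# Methods

## Signal model and preprocessing

A `Recording` holds a channels × samples matrix in microvolts with one
sampling rate, channel labels and seizure annotations. Preprocessing
for the coupling-inference path follows standard scalp-EEG practice:
per-channel mean removal, common average reference, and a zero-phase
4th-order Butterworth band-pass (1–50 Hz, forward–backward). The
spectral path does not need the band-pass — its own band restriction
discards out-of-band content — so it consumes raw data scaled into
[−1, 1] by default. Scaling is per channel by the channel's maximum
absolute value over the whole recording (a per-recording global scale is
available); per-channel scaling keeps low-amplitude channels
informative. Both orders (raw vs pre-filtered input to the spectral
path) are exposed through `FTConfig.prefilter`.

Idempotence caveat: a Butterworth band-pass is not exactly flat at its
edges, so "preprocess twice = preprocess once" holds only for signals
whose energy sits well inside the passband and away from the filter's
edge transients (the 1 Hz high-pass rings for several seconds). The
idempotence test therefore uses mid-band tones and trims 8 s margins.

Windows are half-open sample ranges `[start, end)`, non-overlapping by
default, timestamped at the window *end* (the moment the window's
verdict becomes available to a causal detector). Trailing partial
windows are dropped.

## The spectral synchronization network

Per window (default 1 s), the one-sided FFT of each channel (rectangular
window, no zero-padding, no 1/N normalization) gives magnitudes
`p = |X|` and phases. Outside the analysis band (default 2–10 Hz,
inclusive edges, 1/w Hz resolution) magnitudes are zeroed. Then

* `P_i = Σ p²` (band energy),
* `σᵖ_ij = P_i + P_j` — symmetric, nonnegative,
* `σᵠ_ij = mean_n sin(φ_jn − φ_in)` — antisymmetric, |σᵠ| ≤ 1,
* `d_ij = σᵖ_ij σᵠ_ij`, `d_ii = 0`,
* `a_ij = 1 − exp(−|d_ij|^γ)` with γ = 2; `L = diag(row sums) − A`.

λ₂ is computed by a dense symmetric eigensolver (n = 23 channels makes
cost negligible; ~3600 windows/hour solve in seconds). Numerical
choices: `a_ij` is clamped to the largest double below 1 so the open
interval [0, 1) survives exponent underflow; eigenvalues in
(−10⁻¹², 0) are clamped to zero; the eigenratio λ₂/λₙ is defined as 0
for an empty graph.

Two conventions deliberately left as options:

* `power_def`: `magnitude` (p = |X|, so `P ∝ amplitude²`; default,
  matching the Parseval/RMS-power analogy that motivates the method) or
  `periodogram` (p = |X|², `P ∝ amplitude⁴`).
* `P` is *not* normalized by window length; detection thresholds are
  calibrated per recording anyway.

Why this rejects artifacts but catches seizures: σᵠ is a lag measure —
zero-lag (or π-lag) common activity cancels, and random-phase transients
average to small values with fluctuations ∝ 1/√N over the N band bins —
while the power factor σᵖ only matters where a consistent lag exists.
A transient confined to k of n channels can, at most, attach k strong
hubs to the graph; λ₂ of a graph whose remaining n−k nodes are weakly
connected is capped near `λ₂(background) + k·(1 − a_bg)` no matter how
much power the transient carries. A seizure, by contrast, saturates
`a_ij → 1` for *all* pairs (any consistent nonzero lag, multiplied by
the large band energies, drives |d| ≫ 1), pushing λ₂ toward its maximum
n·max(a) ≈ n. The detector threshold sits between the artifact cap and
the seizure plateau by construction of the mean + k·std calibration.

A known blind spot, documented rather than patched: perfectly
phase-aligned channels (lag exactly zero) give σᵠ = 0 and λ₂ = 0, and
seizures that begin with amplitude depression produce no band-power
surge at all; the spectral feature cannot see either.

## Coupling-function inference

The dynamics of channel i is expanded as
`ẋᵢ = Σ_k a_k Q_k(xᵢ) + Σ_{j≠i} Σ_{kl} b_ij^{kl} P_k(xᵢ) P_l(xⱼ)` with
`Q = P` a truncated trigonometric set on the normalized state
(`u = (x+1)/2`): `{1, sin 2πu, cos 2πu, sin 4πu, cos 4πu}` for r = 5.
For phase data wrapped to [−π, π) and scaled by 1/π, the first harmonic
pair spans sin/cos of the phase itself, so Kuramoto-type coupling
`K sin(xⱼ − xᵢ)` lies exactly in the product span.

Per window and channel, the design matrix has `C = r + r²(N−1)` columns
(r self columns, then one r² block per source channel, (k, l)
row-major). Derivatives are central differences (one-sided at the
ends). The least-squares problem is solved by SVD.

**Identifiability and canonical form.** The products `P_k(xᵢ)·P_0(xⱼ)`
do not depend on the source channel (the first basis function is the
constant 1) and exactly duplicate the self columns, so the design has a
structural null space of dimension r per source channel and the
coefficient vector is only determined up to shuffling weight between
those copies. `coupling_strengths` therefore reports a *canonical form*:
every `b_ij^{k0}` is folded into `a_k` and the l = 0 column of each
block zeroed. This linear map annihilates exactly the structural null
space, so canonical coefficients are identifiable, recovered exactly
from noiseless in-span data, and — importantly — coupling strengths are
not inflated by self-dynamics leaking into constant products. A
coupling component that does not depend on the source state is
attributed to self-dynamics, which is the only defensible reading.

**Spectral cutoff.** A window covers only part of the joint state
space, so beyond the structural null space the design has a long tail
of tiny singular values; inverting them amplifies derivative noise into
large spurious couplings. `infer_network` truncates singular values
below `rcond = 10⁻³` of the largest by default (`rcond=None` restores
the pure minimum-norm solve used by the noiseless consistency checks).
An optional Tikhonov ridge is also available (auto-escalated with a
warning if the normal matrix is numerically singular).

**Aggregation across windows.** α is a norm, so per-window estimation
noise biases it upward and survives averaging of per-window α values;
`average_coupling` averages the signed coefficient blocks across
windows *before* taking the root-sum-square, which cancels noise.

λ₂ is extracted from the symmetrized strength matrix `W = (J + Jᵀ)/2`
(a Fiedler eigenvalue needs a symmetric Laplacian; α is directed), and
smoothed as `ema_t = β λ₂(t) + (1−β) ema_{t−1}`, `ema_0 = λ₂(0)`, with
β = 0.2 by default (β = 1 reduces to the raw series; the EMA is bounded
by the raw extremes and fixes constants).

One structural note: the column count `r + r²(N−1)` follows from the
expansion itself; an alternative bookkeeping that counts `r²N + 1`
coefficients per channel appears in some descriptions of this estimator
and is not consistent with the expansion's block structure; this
implementation uses the former.

## Detection and evaluation

An event starts at the first of ≥ τ_d (default 6 s) consecutive
super-threshold seconds; its onset is the *first crossing* (not the
confirmation), so delay `d = onset − annotated onset` and latency
`L = d + τ_d` separate cleanly. Confirmed events closer than `min_gap`
(default 10 s) merge. The threshold is `mean + k·std` (k = 6) of a
seizure-free baseline, optionally percentile-clipped; a causal
moving-average variant is provided. Scoring is event-based: an event is
a true positive if its onset falls within
`[annotated onset − 10 s, annotated offset]` (annotated onsets are
imprecise, and detections slightly before the mark must count); at most
one TP per seizure, surplus events inside a seizure are collapsed, all
other events are false positives counted per merged event. Aggregation
across patients pools the counts (`S = 100·ΣTP/ΣNS` is order-invariant)
and offers both unweighted and TP-weighted means of the per-patient
latency/delay columns, since both conventions appear in published
benchmark tables; the two are labeled, never mixed.

## Synthetic data: what it emulates and what it does not

`gen_recording` is a phenomenology generator, not an EEG forward model.
Background is built from three zero-lag shared pink (1/f) sources mixed
with random positive gains (a volume-conduction-like common component:
large power, near-zero lags), a small per-channel pink jitter, and a
weak 9–11 Hz rhythm with i.i.d. frequency and phase per channel whose
lower edge reaches into the 2–10 Hz analysis band. Defaults
(shared 5 µV RMS per source, jitter 1 µV, rhythm 1 µV) were chosen once
so the band is quiet at rest: resting λ₂ sits near 1–2 with standard
deviation a few tenths — low enough that a seizure's λ₂ ≈ n is tens of
standard deviations away, high enough that the k = 6 calibrated
threshold clears the few-channel artifact cap described above.

Seizures are coherent tones (default 6 Hz, 300 µV) on all channels with
fixed per-channel lags `π/4 · i/n` and 1 s amplitude ramps; lag zero is
kept available as the documented adversarial case (λ₂ blind spot).
Artifacts are 2 s, 1500 µV band-limited (2–24 Hz) noise bursts on two
random channels — their random phases give them no consistent lag
structure. Because each channel is normalized by its own peak, a
23-channel coherent seizure necessarily dominates any 2-channel
artifact in *normalized* total band power; the "artifact power surge
exceeds seizure power surge" phenomenon is therefore asserted on the
raw (microvolt) spectra, which is also where a simple summed-power
feature would be computed. All generators are pure functions of
(config, seed).

`simulate_oscillators` integrates phase networks
`ẋᵢ = ωᵢ + Σ K_ij sin(xⱼ − xᵢ)` with fixed-step RK4 plus optional
per-step Gaussian noise, exporting unwrapped phases (or sin thereof)
and the true coupling matrix. `random_oscillator_network` encodes the
*identifiable drift regime* used by the recovery studies: natural
frequencies spread over 1.5–6 rad/s and coupling weights 0.3–0.6, kept
below pairwise frequency differences so no pair phase-locks — a locked
pair's phase difference is constant, its coupling term indistinguishable
from self-dynamics, and the edge unrecoverable *in principle*, not just
in practice. Small dynamical noise (0.005) aids torus exploration. In
this regime, edge ranking by recovered α attains mean ROC AUC ≈ 0.99
over seeded 6-node networks.

What passing tests do and do not show: the synthetic background has no
heavy-tailed amplitude epochs, no electrode pops, no line noise, no
non-stationary rhythms, and seizures are stationary tones rather than
evolving spike-wave complexes. Success here demonstrates the
*mechanism* (lag-weighted power graphs separate coherent
hypersynchronization from incoherent power), not clinical performance;
per-patient results on real scalp EEG require the real recordings.

## Problem sizes and runtime

Default study sizes: the detection suite uses one hour at 256 Hz ×
23 channels (3600 windows); artifact-rejection statistics use 100
seeded 2-minute trials; coupling recovery uses 40 s simulations at
200 Hz with two 20 s windows, 20 seeds. The full test suite runs in
about a minute on one CPU; the acceptance script in ~25 s.

## Known limitations

* The spectral feature is blind to zero-lag synchronization and to
  amplitude-depression seizure onsets (both documented above).
* Threshold calibration assumes a seizure-free (though not
  artifact-free) baseline segment is identifiable.
* The coupling model is first-order in the state and pairwise;
  higher-order or delayed interactions alias into the pairwise terms.
* EDF output quantizes to 16 bits of each channel's physical range;
  CSV fixtures round-trip exactly.
* No wavelet variant, no per-channel localization, no online/streaming
  service mode (real-time capability is a per-window latency property,
  demonstrated by the 1 s windows, not a daemon).
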