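# Methods

## Signal model and scope

The package treats a single abdominal channel as the additive mixture
`AbdECG = MECG + FECG + Noise`: a dominant maternal ECG, a faster
low-amplitude fetal ECG, and noise (baseline wander from breathing,
broadband sensor noise, powerline hum).  Processing is strictly
per-channel; multichannel fusion, maternal-template subtraction and
Kalman/ICA-style source separation are out of scope.

## Wavelet kernels

Four explicit mother wavelets are implemented in dimensionless time:
Haar (`+1` on [0, 1/2), `−1` on [1/2, 1); the value at 1/2 belongs to the
negative half, intervals are right-open), Faber–Schauder
(`(Λ(2t) − 2Λ(2t−1) + Λ(2t−2))/2`, support (−1/2, 3/2)), and the two
Clifford–Hermite–Jacobi wavelets with radial profiles
`(−2r + r³)` and `(r + 16r³ + 24r⁵ + 13r⁷ + r⁹)` against the weight
`(1+r²)^{3/2} e^{−r²/2}`.

The Clifford wavelets are defined on R³ with a vector direction; their
one-dimensional restriction here is the **odd** extension
`sign(t)·p(|t|)·ω(|t|)`, because the vector part of an odd monogenic
polynomial reverses with direction and because oddness guarantees zero
mean (admissibility).  The even (radial) restriction would not be
admissible.  The weight `(1+r²)^{3/2}` is a multiplicative factor, not a
denominator.  Normalization constants are computed by adaptive quadrature
at construction and cached; Gaussian-decay kernels are truncated at
`|t| ≥ 10`, where their magnitude is below 1e−12.

Two-order banks pair kernels — `hfsch = (Haar, Faber–Schauder)`,
`clifford = (ψ₁, ψ₂)` — whose components analyze the signal independently;
bank reconstructions are the **mean** of the component reconstructions.
(The literal two-component superposition would count the signal twice;
averaging keeps the output on the input scale.)

## Discretization and frame synthesis

The time axis is affinely rescaled to [0, 1]; level `j` (larger = finer)
uses dilates `2^{j/2} ψ(2^j u − k)` at integer positions spaced `2^{−j}`,
and coefficients are rectangle-rule inner products against the sampled,
Euclid-normalized atoms (`d_{j,k} = Σ_n X[n] ψ_{j,k}(n/N) / √N`).  With
this convention the Haar system on dyadic lengths is exactly orthonormal:
round trips are machine-precision and `Σ d² + ‖residual‖² = ‖X‖²`.
Signals are extended by reflection at the boundaries; the coarse residual
is the mean (the content below level 0).  The deepest level is capped one
octave below the dyadic limit so the finest atoms still span at least two
samples.

The Faber–Schauder system and the Clifford translates are frames, not
bases.  Synthesis with the plain adjoint plus per-level scalar gains was
evaluated first and rejected: even with gains least-squares-fitted on the
test signal itself, round-trip errors are 6 % (ψ₁ on an in-band sine) to
21 % (Faber–Schauder on white noise), because the Clifford spectra have
genuine nulls, within-level translates are heavily redundant, and the
Faber–Schauder expansion needs its biorthogonal dual.  The implementation
therefore inverts the frame operator `T = Σ_j V_jᵀ V_j` spectrally: a
cached eigendecomposition per (kernel, length, depth) gives a truncated
pseudo-inverse — directions whose frame eigenvalue is below `1e−3` of the
largest are **dropped**, not amplified, since they are outside the frame's
stable reach — and the dual signal `z` then yields level details
`D_j = g_j V_jᵀ V_j z`.  The constant direction, annihilated by every
zero-mean kernel, is deflated explicitly and carried by the coarse
residual.  The spectral cutoff is the key stability parameter: with a tiny
ridge instead, weakly covered directions inflate the per-level partial
sums by orders of magnitude even though the full sum cancels.

The per-level gains `g_j` are measured amplitude corrections: a probe
sinusoid at each level's passband center (the peak of the central atom's
spectrum) is pushed through the full analysis–synthesis chain and the
gain is the reciprocal of the amplitude ratio, clipped to [0.1, 10].  For
orthonormal Haar at full depth the chain is an orthogonal projection and
all gains are 1; at partial depth they compensate truncation.  A level
with negligible probe response raises a calibration error naming the
level.

Measured round-trip accuracy after these choices: Haar machine precision;
ψ₁ on a 5 Hz test sine at 250 Hz about 2e−3; the Haar/Faber–Schauder bank
on dyadic white noise below 1e−8; the Clifford bank on 5–20 Hz band-limited
noise below 1e−3.

## Wavelet entropy and level selection

Level energies sum squared detail coefficients over positions and bank
components; probabilities use the total over **all** computed levels as a
fixed denominator, so `Ent(J) = −Σ_{j≤J} p_j ln p_j` is a non-decreasing
partial sum bounded by `ln(levels)`.  Natural logarithms are used; any
base change rescales the curve uniformly and cannot move the plateau.
The detail coefficients (not scaling coefficients) enter the energies,
consistent with the spectral-entropy tradition the construction follows.

The working level is selected as the **first level from which the curve
stays stationary to the end**, with a relative tolerance (default 1 % of
the final value).  A first-small-step rule was considered and rejected:
band-passed signals have entropy curves that are flat at the start (the
coarse levels carry no energy), which would trigger a spurious selection
at J = 1.  A degenerate all-zero curve selects 0 with a warning.

## Extraction pipeline

1. Zero-phase 4th-order Butterworth band-pass, 5–20 Hz, mean removed.
   Zero-phase filtering preserves R-peak timing.
2. Bank decomposition at full depth; working level `J` from the entropy
   plateau (or fixed by the user).  Maternal estimate = reconstruction of
   the approximation part (coarse residual + details below `J`), averaged
   over components.
3. Second decomposition of the maternal estimate with the same bank and
   depth; `App3 = App1 − App2` coefficient-wise at the approximation
   levels.  Every step is linear, so this equals the difference of the
   reconstructed approximations exactly (the bookkeeping identity
   `App2 + FECG = App1` holds to machine precision).  The same level is
   used for both passes.
4. Relative-threshold peak detection on the fetal estimate
   (0.5 × 99th-percentile amplitude, 0.25 s refractory interval — a
   240 bpm physiological ceiling; 0.4 s is the maternal default).

All thresholds are relative, so the pipeline is equivariant under
amplitude scaling: scaling the input scales the estimates and leaves
detected peak times unchanged.

## Detector scoring

Greedy nearest-time one-to-one matching within ±20 ms (±150 ms available
for standard-compliant scoring); ties break toward the earlier reference.
On small instances the greedy matcher agrees with brute-force maximum
bipartite matching in over 99 % of random trials.  Metrics follow the
printed formulas on the percent scale; with TD = 0 the undefined F1 is
reported as 0 with a warning.  Count identities `TD+FN = |reference|`,
`TD+FP = |detected|` and the bound `Accuracy ≤ min(Se, PPV)` are enforced
by property tests.

## Synthetic generator

Beats are sums of five Gaussian deflections (P, Q, R, S, T) with centers
and widths proportional to the RR interval; defaults give a QRS duration
of ~90 ms for the 80 bpm maternal beat and ~45 ms for the 132 bpm fetal
beat — the physiological adult and mid-gestation values — so the fetal
QRS is genuinely the higher-frequency event.  RR intervals carry 3 %
multiplicative Gaussian jitter (clipped at ±3σ); the fetal R amplitude is
0.25 of the maternal; noise is white (σ = 0.05), plus 0.1 baseline wander
at 0.3 Hz and 0.02 powerline at 50 Hz; 250 Hz sampling, 10 s records.
Annotations are the arg-max of the clean component within ±40 ms of each
nominal beat center, and `abd = mecg + fecg + noise` holds exactly.  All
randomness flows through one seeded generator; identical seeds give
bit-identical records.

What the generator does **not** emulate: electrode geometry and fetal
presentation, uterine EMG, waveform variability beyond RR jitter,
non-stationary noise, and any correlation between maternal and fetal
rhythms.  Passing tests therefore demonstrate algorithmic correctness
under the stated mixture model, not clinical performance.

## Known limitations

The central one is quantitative and affects the synthetic-recovery study:
within the 5–20 Hz analysis band, a maternal ECG with physiological QRS
width exceeds a 0.25-amplitude fetal ECG at **every** frequency (fetal
spectral dominance begins only above roughly 25–30 Hz, which the
pre-filter removes).  Any purely linear cancellation — approximation
subtraction included — therefore leaves a residue dominated by the
maternal rhythm, and the relative-threshold detector locks onto it: on
default synthetic records the pipeline recovers the maternal rate
(≈78 bpm) rather than the fetal one, with fetal sensitivity around
5–15 % (the acceptance script reports the exact values it measures).
Coefficient-magnitude thresholding was evaluated as an alternative
maternal estimator and separates only at ratio ≈1 because frames smear
the maternal energy across many coefficients.  Closing this gap requires
maternal-adaptive (nonlinear) cancellation — template subtraction or
gating on the detected maternal peaks — which is outside this package's
scope.

Further limitations: the dyadic ladder offers octave-granular cutoffs
only, so the approximation/detail split cannot be placed precisely within
the analysis band (on a 10 s record the octave boundaries nearest the
band top sit at ≈8.4 and ≈16.8 Hz); content at the Clifford kernels'
spectral nulls is unrecoverable by construction; and the spectral
factorization makes the first analysis for a given (kernel, length,
depth) combination take a few seconds (cached thereafter).

## Problem sizes

Unit and property tests run on 64–512-sample signals; pipeline and
recovery studies use the generator defaults (10 s at 250 Hz) with ten
seeds per condition and a four-point white-noise sweep.  The full test
suite completes in well under a minute on one CPU; the acceptance script
in a few seconds.
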