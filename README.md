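# fetalwave

Fetal ECG extraction from single-channel abdominal recordings using
explicit wavelet and two-order multiwavelet banks, wavelet-energy Shannon
entropy for decomposition-level selection, maternal-ECG cancellation by
approximation subtraction, and R-peak detector scoring.

The package is aimed at biomedical-signal researchers who want a fully
inspectable, dependency-light reference implementation of this family of
methods, together with a seeded synthetic abdominal-ECG generator so the
whole pipeline can be exercised and scored without access to clinical
databases.

## The method

An abdominal recording is modeled as an additive mixture

```
AbdECG(t) = MECG(t) + FECG(t) + Noise(t),
```

where the maternal ECG carries most of the energy and the fetal ECG is a
faster, low-amplitude rhythm (normal fetal heart rate 120–160 bpm).

**Wavelet banks.** Four explicit mother wavelets are provided, singly or
paired into two-order multiwavelet banks whose components act as
independent analyzers ("two blind cameras") and whose reconstructions are
averaged:

* Haar: `ψ_H = χ_[0,1/2) − χ_[1/2,1)`;
* Faber–Schauder: `2 ψ_FSch(x) = Λ(2x) − 2Λ(2x−1) + Λ(2x−2)` with the hat
  `Λ(x) = max(0, 1−|x|)`;
* two Clifford wavelets from the Clifford–Hermite–Jacobi construction with
  weight `(1+|x|²)^{3/2} e^{−|x|²/2}`, restricted to a line through the
  origin as odd functions:

```
ψ₁(t) = C₁ sign(t) (−2r + r³) (1+r²)^{3/2} e^{−r²/2},          r = |t|,
ψ₂(t) = C₂ sign(t) (r + 16r³ + 24r⁵ + 13r⁷ + r⁹) (1+r²)^{3/2} e^{−r²/2},
```

with `C₁, C₂` the L²-normalization constants (computed by quadrature).
The banks are `hfsch = (ψ_H, ψ_FSch)` and `clifford = (ψ₁, ψ₂)`.

**Analysis.** Detail coefficients at level `j`, position `k` are inner
products with the L²-normalized dilates `ψ_{j,k}(u) = 2^{j/2} ψ(2^j u − k)`
on the time axis rescaled to [0, 1]; the level-`J` approximation is the
coarse residual plus all details below level `J`, and `S_J = A_J + D_J`.
Non-orthogonal kernels form frames; synthesis inverts the frame operator
(see `docs/methods.md`).

**Level selection.** With level energies `E_j = Σ_k ‖d_{j,k}‖²` (summed
over bank components), probabilities `p_j = E_j / Σ_j E_j`, the wavelet
entropy is the partial sum `Ent(J) = −Σ_{j≤J} p_j ln p_j`.  The curve is
non-decreasing and bounded by `ln(levels)`; the working level is the first
level from which it is stationary.

**Extraction.** The abdominal signal is band-passed to 5–20 Hz
(zero-phase), decomposed, and the reconstruction of its approximation part
is taken as the maternal estimate; a second decomposition of that estimate
gives `App2`, and the fetal estimate is the reconstruction of
`App3 = App1 − App2`.  Fetal R-peaks are detected on the fetal estimate by
a relative threshold (0.5 × the 99th-percentile amplitude) with a 0.25 s
refractory interval.

**Scoring.** Detections are matched to reference annotations one-to-one
within ±20 ms; with TD/FP/FN the matched, spurious and missed counts:

```
FHR = detections / duration × 60                     Se  = TD/(TD+FN) × 100
Accuracy = TD/(TD+FP+FN) × 100                       PPV = TD/(TD+FP) × 100
F1 = 2·PPV·Se/(PPV+Se)
```

## Worked example

```bash
fetalwave simulate --seed 7 --out-record rec.csv --out-annotations ann.csv
fetalwave extract  --input rec.csv --format csv --channel 0 --out-peaks det.csv
fetalwave evaluate --detected det.csv --reference ann.csv --tol-ms 20 \
                   --duration 10 --report rep.json
```

prints

```
J_used=10 peaks=13 fhr_bpm=78.00
TD=3 FP=10 FN=19 Se=13.64 PPV=23.08 Acc=9.38 F1=17.14
```

The first line says the entropy criterion settled on decomposition level
10 and that 13 peaks were detected on the fetal estimate, a rate of
78 bpm.  The scoring line compares those detections with the 22 annotated
fetal beats of the simulated record: 3 coincide within ±20 ms, 10 are
spurious and 19 fetal beats are missed.  At these study conditions
(fetal/maternal amplitude ratio 0.25, physiological QRS morphology, 5–20 Hz
pre-filter) the subtraction residue is dominated by the maternal rhythm —
the detected 78 bpm is the maternal rate — which is the central practical
limitation of purely linear approximation subtraction; `docs/methods.md`
discusses why.

The detector scoring itself reproduces reference values exactly: for
counts TD=9573, FP=639, FN=596 the package computes
Accuracy 88.57 %, Se 94.14 %, PPV 93.74 %, F1 93.94, and 22 peaks over a
10 s record give FHR = 132 bpm.

The library surface mirrors the CLI: `fetalwave.generate`,
`fetalwave.extract_fecg`, `fetalwave.match_peaks`, `fetalwave.metrics`,
plus two scikit-learn estimators (`FetalECGExtractor`,
`WaveletEnergyTransformer`) that compose with sklearn pipelines.

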