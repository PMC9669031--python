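# emgmod

Modular complexity analysis of multi-muscle EMG envelopes during cyclic
locomotion: muscle-synergy factorization with noise-robust
dimensionality selection, periodic/aperiodic spectral parameterization,
per-stride module clustering, and intermuscular coherence networks —
plus a synthetic-data generator with known modular ground truth, so
every stage is testable without any recording.

## Who this is for

Motor-control and developmental-neuroscience researchers who extract
neuromuscular modules from surface EMG of stepping or walking (typical
setup: bilateral BF, RF, LG, TA; strides time-normalized to a 200-point
cycle) and need to know how many modules the data support *in the
presence of noise* — the regime where fixed VAF thresholds are known to
mislead.

## The core idea

Three factorization models of the stride-indexed envelope matrix, all
solved by nonnegative factorization (best of many restarts):

- **spatial** — m^s(t) = Σᵢ cᵢˢ(t) wᵢ (shared synergies w, per-stride
  patterns c);
- **temporal** — m^s(t) = Σᵢ cᵢ(t) wᵢˢ (shared patterns, per-stride
  synergies);
- **space-by-time** — m^s(t) = Σᵢⱼ cᵢ(t) aᵢⱼˢ wⱼ, a sample-based
  tri-factorization in which an N×N nonnegative coefficient matrix Aˢ
  couples shared patterns to shared synergies on every stride.

Instead of thresholding VAF, dimensionality is read from a
*consistency* measure across strides — pattern similarity, synergy
similarity, or the diagonality d = trace(A)/ΣA of the coefficient
matrix — as a function of the module count N. The N at the maximum
slope (the largest drop caused by adding one module) identifies the
generating dimensionality and stays stable across noise levels where
VAF-based criteria drift. Single-muscle complexity is quantified by
modeling each envelope PSD as a Lorentzian aperiodic background
b − ln(k + f^χ) plus Gaussian peaks (with corrected offset b* = b − ln k
and knee k* = k^{1/χ}) and by normalized spectral entropy; inter-muscle
coupling in the frequency domain is summarized by NMF of the pairwise
magnitude-squared-coherence matrix into frequency components and
weighted muscle networks.

## Worked example

Generate a 3-module dataset corrupted by signal-dependent noise
(SD = η·signal), then recover its dimensionality:

```python
import numpy as np
import emgmod as em

mods = em.generate_modules(n_modules=3, n_muscles=8, seed=1)
ds = em.simulate_emg(mods, eta=0.9, seed=2)
print(f"fidelity r2: {ds.fidelity_r2:.3f}")

res = em.sort_modules(
    em.decompose(ds.noisy, "space_by_time", "nnmf", n_modules=3, restarts=20, seed=4)
)
print(f"VAF at N=3: {res.vaf:.1f}%")
print(f"mean diagonality: {em.stride_consistency(res):.3f}")

curve = em.consistency_curve(
    ds.noisy, model="space_by_time", algorithm="nnmf", restarts=20, seed=3
)
print(f"selected modules: {curve.selected_n}")
print("diagonality by N:", np.round(curve.values, 3))

freqs, psd = em.compute_psd(ds.noisy)
fit = em.fit_psd_model(freqs, psd[0])
print(f"BF spectrum: {fit.n_peaks} peaks, spectral entropy {fit.spectral_entropy:.2f}")
```

prints

```
fidelity r2: 0.879
VAF at N=3: 91.5%
mean diagonality: 0.922
selected modules: 3
diagonality by N: [1.    0.982 0.919 0.65  0.543 0.472 0.429 0.362]
BF spectrum: 4 peaks, spectral entropy 0.27
```

Reading it: the noise level η = 0.9 leaves the corrupted data at
r² ≈ 0.88 against the noiseless ground truth. Fitting the space-by-time
model at the true N = 3 explains 91.5% of the (uncentered) variance,
and the per-stride coefficient matrices are strongly diagonal (0.92):
each temporal pattern drives mostly its own synergy on every stride.
The diagonality curve stays high up to N = 3 and collapses at N = 4
(0.92 → 0.65) — the maximum-slope criterion therefore selects 3, the
number of modules that generated the data. The spectral fit of the
first muscle finds 4 periodic peaks (harmonics of the stride rate) with
low spectral entropy, i.e. a strongly rhythmic envelope.

Estimator-style classes (`ModularDecomposition`, `SpectralModel`,
`ModuleKMeans`, `CoherenceNMF`) expose the same functionality with
sklearn-style `fit`/`get_params` conventions; the module-level functions
above are thin wrappers over them.

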