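# Methods

This document records the signal model, conventions and numerical choices
implemented in `breathfield`.

## 1. Physical model

Breathing modulates the B0 field near the cervical spinal cord. The
correction assumes the fluctuation is separable in space and time:

```
ΔB0(z, t) = R(t) · ΔBref(z)        [Hz]
```

where `R(t)` is the (dimensionless, baseline-removed) respiratory bellows
signal and `ΔBref(z)` is a per-slice coupling profile in Hz per bellows
unit. The profile grows toward inferior slices, where the thorax is
closer; the simulator's default spans 4 Hz/unit at the most superior slice
to 10 Hz/unit at z = 21 mm.

A field offset `f0` present during a readout acquired `t_ro` seconds after
excitation adds phase `Δϕ = 2π · f0 · t_ro` to that k-space line. The
correction demodulates each line:

```
ŝ(k) = s(k) · exp(−i · 2π · f0(z, t_eval) · t_ro)
```

The field is treated as static over one readout train. `t_eval` is the
excitation time for multi-echo gradient echo (each echo of the train uses
its own `t_ro = TE_e`), and excitation + TE for EPI shots (the centre of
the echo train, which dominates image contrast).

One global sign convention (`PHASE_SIGN = +1`) is shared by the simulator,
the calibration and the corrector, so the demodulation exactly inverts the
simulated modulation.

## 2. Calibration

The calibration input is a dynamic single-slice sagittal FLASH series
(TE 4.08 ms, one volume every 344 ms, 64×43), giving 10–22 field samples
per breathing cycle for periods between 3.6 and 7.7 s.

Per voxel, with temporal phase unwrapping (`np.unwrap` along time):

```
ΔB0(r, t_i) = (ϕ(r, t_i) − ϕ̄(r)) / (2π · TE)      [Hz]
```

The temporal mean ϕ̄ removes the static (anatomical + shim) phase. The
field is averaged over a cord mask per z row, producing a per-row time
series `f0(z, t_i)`; rows with an empty mask are dropped with a warning.

**Coupling fit.** The bellows trace is synchronized to the scan clock at
the trigger mark, baseline-removed, and linearly interpolated to the frame
times. For each z the scalar coupling is the least-squares solution of
`f0(z, t_i) ≈ c(z) · R(t_i)` over a fit window (default 30 s from the
record start). Both the trace and the field are demeaned **over the
retained window frames** before the solve. Rationale: the per-voxel field
is zero-mean over the whole record while the windowed trace generally is
not; without window demeaning the scalar fit would absorb that baseline
mismatch into `c(z)` and a noiseless simulation would not be recovered
exactly. With it, noiseless recovery is exact to ~1e−16 and the toy case
`R = [1,2,3]`, `f0 = [2,4,6]` still yields `c = 2` exactly.

**Swallow rejection.** Swallowing produces field bursts (up to ~40 Hz,
1–2 s) uncorrelated with the bellows. A provisional fit is computed, and
frames whose residual exceeds `k = 4` robust standard deviations
(1.4826 × MAD) in any slice are excluded; the fit is then repeated. The
false-positive rate of this rule on clean data is below 1% per frame.

## 3. Correction

- `sync_trace` rebases the trace clock so the chosen trigger mark is t = 0
  of the sequence clock and removes the mean value.
- `predict_field` evaluates `ĉ(z) · R(t)` at the per-excitation evaluation
  times; events outside the trace support hold the edge value with a
  warning; slices absent from the calibration grid use the nearest
  calibrated z with a warning.
- `demodulate` applies `exp(−i·2π·f0·t_ro)` per line (and `remodulate`
  inverts it). Magnitude is preserved to the last floating-point digit.

## 4. Reconstruction

- Centered unitary FFT convention: `fft2c = fftshift ∘ fft2(norm="ortho")
  ∘ ifftshift`, DC at index `floor(N/2)`.
- **CG-SENSE**: conjugate gradients on the normal equations of
  `E = M F S` (sampling mask, Fourier transform, coil sensitivities).
  Defaults `n_iter = 30`, `tol = 1e−9` for noiseless work and `1e−6` for
  noisy time series. All repetitions and echoes of a slice that share a
  sampling pattern are solved as one batched CG with per-item stopping;
  for even matrix sizes the normal operator runs on unshifted FFTs with a
  permuted row mask (the shift permutations commute with the circulant
  operator), which is numerically identical and measurably faster.
  Divergence (three consecutive residual increases) raises an error.
- **EPI reference correction**: reversed-polarity (odd) train lines are
  corrected by a constant + linear phase per slice in hybrid (x, k_y)
  space, the standard Nyquist-ghost model. A container flag guards against
  double application.
- **Echo combination**: root-sum-of-squares across echoes, insensitive to
  per-echo global phase.

## 5. Quantification

- **T2\***: voxelwise monoexponential fit `S(TE) = S0 · exp(−TE/T2*)` on
  magnitudes, log-linear initialization, bounded (0.1–500 ms) trust-region
  least squares. No noise-floor offset term: the Rician bias of the plain
  model is accepted and measured (median bias < 10% at SNR 20 over the
  10-echo protocol).
- **tSNR**: temporal mean / sample SD (ddof = 1); voxels with zero SD are
  undefined (NaN), never infinite.
- **Ghost metric**: mean |signal| outside the 2-voxel-dilated object mask
  divided by mean |signal| inside the cord mask; scale invariant.
- **ROI statistics**: median, P5/P25/P75/P95 (linear interpolation), mean;
  NaN (invalid fit) voxels excluded.

## 6. Simulator

The simulator generates every pipeline input with retained ground truth:

- **Phantom**: elliptical neck cross-section with CSF ring and cord
  (cord T2* 25 ms, tissue 15 ms, CSF 45 ms), ±2% smooth proton-density
  texture, configurable slice positions.
- **Trace**: quasi-periodic sinusoid with per-cycle period jitter
  (4.5 ± 0.4 s by default) and 10% amplitude jitter, sampled at 50 Hz with
  trigger marks; `R(t)` drives the field through the coupling profile.
- **Coupling profile**: closed form in absolute z
  (`base + gradient · z`), so nested z grids agree at shared points.
- **FLASH**: one frame per volume TR at the frame mid-time; voxel phase is
  a static random phase plus `2π · TE · f0(z_row, t)` on a fine sagittal z
  grid spanning the slice stack.
- **MEGRE / EPI4**: per-line k-space synthesis. The decayed coil-weighted
  object is Fourier transformed once per distinct readout time; the
  acquired row is multiplied by the line's field phase. The 4-shot EPI
  interleave assigns shot m, train position i the row `R·(m + 4i)` at
  `t_ro = TE + (i − n_line/2)·esp`, with odd positions reversed and
  optionally carrying an injected odd/even phase discrepancy.
- **Clean twin**: each acquisition is returned with a fluctuation-free
  twin computed with the *identical* noise realization, so oracle
  correction must match it to numerical precision — the strongest
  end-to-end invariant in the test suite.

Swallow bursts and an optional link-noise term deliberately break the
trace–field link to exercise outlier rejection and robustness.

## 7. Problem sizes and budgets

The headline experiments use 64×64 matrices: 8 slices for the multi-echo
scan, 3 slices spanning the coupling range (z = 0, 9, 18 mm) for the
120-volume EPI time series. These sizes keep the full test suite and the
`scripts/acceptance.py` sweep within a few minutes on a single CPU while
preserving every structural property of the protocol (10 printed TEs,
4 shots × 650 ms shot TR = 2.6 s volume TR, SENSE factor 2).
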