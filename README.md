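# breathfield

Retrospective correction of breathing-induced B0 field fluctuations in
multi-shot T2*-weighted MRI of the cervical spinal cord.

Breathing moves the lungs and chest wall, which modulates the magnetic
field near the spinal cord by several Hz at 7T. In multi-shot acquisitions
(multi-echo gradient echo, segmented EPI) the field changes between shots,
so k-space lines acquired at different respiratory states carry
inconsistent phase. The result is ghosting that scatters cord signal,
biases T2* estimates downward and inflates the temporal noise of fMRI time
series. `breathfield` removes this effect retrospectively using only a
respiratory bellows trace:

1. **Calibrate** — a fast dynamic FLASH scan measures the field near the
   cord over ~1 min; a linear model `ΔB0(z, t) = R(t) · ΔBref(z)` is fitted
   between the bellows trace `R(t)` and the measured per-slice field.
2. **Predict** — during the imaging scan, the recorded trace and the fitted
   coupling profile predict the field offset `f0(z, t)` at every excitation.
3. **Demodulate** — each k-space line acquired at readout time `t_ro` after
   excitation is multiplied by `exp(−i·2π·f0·t_ro)`, cancelling the
   breathing-induced phase before reconstruction.
4. **Reconstruct & quantify** — CG-SENSE (or plain FFT) reconstruction,
   monoexponential T2* mapping, temporal SNR and a ghosting metric.

A full acquisition simulator (digital cord phantom, jittered breathing
trace, FLASH / multi-echo GRE / 4-shot EPI with per-line field modulation
and coil sensitivities) generates every input with retained ground truth,
so the whole pipeline is verifiable end to end without scanner data.

## Worked example (library)

```python
from breathfield import (
    BreathingModel, SequenceSpec, calibrate, demodulate, fft_recon,
    fit_t2star, make_phantom, make_trace, predict_field_for_container,
    simulate_acquisition, simulate_flash, summarize_roi,
)
import numpy as np

model = BreathingModel(period_sd_s=0.0)          # sinusoidal breathing
phantom = make_phantom(n_slices=8, seed=0)        # cord T2* = 25 ms

# calibration scan → coupling profile
flash = simulate_flash(phantom, SequenceSpec.flash(),
                       make_trace(60.0, seed=1), model)
calib = calibrate(flash.series, flash.cord_mask, flash.resp)

# imaging scan → predict → demodulate → reconstruct → quantify
sim = simulate_acquisition(phantom, SequenceSpec.megre(),
                           make_trace(80.0, seed=2), model, seed=0)
field = predict_field_for_container(calib, sim.resp, sim.kset)
echoes = np.abs(fft_recon(demodulate(sim.kset, field)).data[0, :, 0])
t2map = fit_t2star(np.moveaxis(echoes, 1, 0),
                   np.asarray(sim.kset.meta["te_ms"]), phantom.cord_mask)
print(summarize_roi(t2map.t2star_ms, phantom.cord_mask)["median"])  # ≈ 25.0
```

Without the demodulation step the same pipeline yields a median cord T2*
of ≈ 17.6 ms — a ~30% underestimate caused purely by shot-to-shot field
inconsistency.

## Worked example (CLI)

```bash
breathfield simulate --config cfg.yaml --out sim/
breathfield calibrate --flash-mag sim/flash_mag.nii.gz \
    --flash-phase sim/flash_phase.nii.gz --meta sim/flash_meta.json \
    --mask sim/flash_mask.nii.gz --trace sim/flash_trace.csv --out calib.json
breathfield correct --kspace sim/kspace.h5 --calib calib.json \
    --trace sim/trace.csv --out corrected.h5
breathfield recon --kspace corrected.h5 --sens-mag sim/sens_mag.nii.gz \
    --sens-phase sim/sens_phase.nii.gz --out img.nii.gz
breathfield t2star --echoes img.nii.gz \
    --tes 3.51,6.68,10.37,14.06,17.75,21.44,25.13,28.82,32.51,36.20 \
    --mask sim/cord_mask.nii.gz --out t2s.nii.gz --report t2s.json
```

## Layout

- `src/breathfield/io.py` — trace CSV, k-space HDF5, NIfTI pairs, masks,
  calibration JSON, YAML config
- `src/breathfield/calibration.py` — temporal unwrapping, phase→field,
  cord-mask averaging, outlier (swallow) rejection, coupling fit
- `src/breathfield/correction.py` — trace sync/resampling, field
  prediction, k-space phase demodulation
- `src/breathfield/reconstruction.py` — centered unitary FFT, CG-SENSE,
  EPI odd/even reference correction, root-sum-of-squares combination
- `src/breathfield/simulation.py` — phantom, trace, coupling profile,
  coil maps, FLASH / MEGRE / EPI simulators with ground truth
- `src/breathfield/analysis.py` — T2* fitting, tSNR, ghost metric, ROI stats
- `src/breathfield/experiments.py` — end-to-end experiments behind the
  headline numbers
- `docs/methods.md` — model, conventions and numerical choices in detail
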