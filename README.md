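# pdsense

Passive bistatic Doppler radar processing for non-contact e-health
monitoring: breathing-rate detection while a person is still, and
recognition of six activities of daily living (walking, running, jumping,
standing, sitting, turning) while they move — from nothing but two
synchronized IQ recordings of an existing in-home RF transmitter.

A passive radar points one antenna at the illuminator (the **reference**
channel) and one at the monitored area (the **surveillance** channel).
Correlating the channels over delay τ and Doppler f_d gives the
cross-ambiguity function, computed batched over an integration window T:

    CAF(τ, f_d) = Σ_k ∫_0^{T_B} x(t) y*(t − kT_B − τ) e^{−j2π f_d t} dt,
    T_B = T / n_b,  Δf_d = 1/T

The dominant zero-Doppler ridge from the direct signal and static clutter
is removed by CLEAN — subtracting the reference's scaled self-ambiguity
surface — and a Doppler spectrogram D(f_d, n) is assembled from each
frame's strongest range cell. A Doppler-power motion indicator then routes
the recording:

* **static** → breathing: the centre-weighted asymmetry statistic
  Ψ(n) = Σ_i D(f_i, n)·w_i (antisymmetric weights about zero Doppler)
  recovers sub-bin chest motion; after Savitzky–Golay smoothing the
  breathing rate is the FFT argmax in the 6–30 bpm band, and the
  integrated waveform is compared to a chest-belt reference (Pearson R,
  MSE).
* **moving** → activity: 4 s spectrogram windows are reduced to SVD,
  PCA, or six physical features and classified by a one-against-one
  ensemble of 15 pairwise linear SVMs with majority voting.

Since no public recordings of such a system exist, the package includes a
full synthetic-scene generator (DSSS illuminator, multipath channel,
breathing chest, six activity velocity templates, a 180-recording
multi-subject corpus) with exact ground truth; every processing stage is
validated against it. See `docs/methods.md` for the model details and all
chosen parameters.

## Worked example

```python
import numpy as np
from pdsense import (breathing_scene, process_recording,
                     analyze_breathing, CAFConfig)

# 30 s scene: subject 40 cm from the antenna, breathing at 17 bpm
ref, surv = breathing_scene(rate_bpm=17.0, seed=7)

spec = process_recording(ref, surv, CAFConfig.breathing())
est = analyze_breathing(spec, belt=np.asarray(surv.truth["belt"]),
                        belt_rate_hz=2.0)
print(f"estimated rate : {est.rate_bpm:.2f} bpm (truth 17.00)")
print(f"belt R / MSE   : {est.r_value:.3f} / {est.mse:.1f}")
```

prints

```
estimated rate : 17.06 bpm (truth 17.00)
belt R / MSE   : 0.953 / 67.6
```

The rate lands within 0.06 bpm of the ground truth and the reconstructed
breathing waveform correlates at R = 0.95 with the simulated chest-belt
displacement (the MSE is in the waveform's arbitrary amplitude units).

The same works from a shell:

```
pdsense simulate --mode breathing --seed 7 --out scene
pdsense process  --ref scene/reference.iq --surv scene/surveillance.iq \
                 --mode breathing --out proc
pdsense breathe  --spectrogram proc/spectrogram_breathing.csv \
                 --belt scene/belt.csv --out out
```

and `pdsense run --ref ... --surv ... --out ...` runs the full
auto-switching pipeline (motion segmentation, then breathing and/or
activity outputs per segment). For activity work, `pdsense simulate --mode
corpus` writes the 180-recording labelled corpus, `pdsense featurize`
extracts per-window features, and `pdsense classify` evaluates repeated
stratified train/test splits.

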