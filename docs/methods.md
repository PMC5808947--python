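# Methods

`pdsense` implements a passive bistatic Doppler radar processing chain for
non-contact health monitoring: an existing in-home transmitter illuminates
the room, one receive channel (reference) records the transmitted waveform
and a second (surveillance) records reflections from the monitored person.
Correlating the two channels over delay and Doppler reveals body motion;
chest-wall micro-motion gives the breathing rate and whole-body motion gives
an activity label. Because no public recordings of such a system exist, the
package ships a first-class synthetic-scene generator with exact ground
truth, and every stage is validated against it.

## 1. Scene model (`pdsense.scene`)

**Illuminator.** A direct-sequence spread-spectrum source
`x(t) = sum_i e^{j phi_i} p(t)` — random ±1 chips spreading random-phase
data bits, shaped by a root-raised-cosine pulse `p(t)` (roll-off 0.25; the
real transmitter's pulse shape is unpublished, so a standard RRC was
chosen). Defaults describe the full-scale device: carrier 915 MHz, occupied
bandwidth 20 MHz, 30 dBm.

**Channel.** The surveillance channel is a sum of delayed, attenuated,
Doppler-modulated copies plus complex AWGN:

    y(t) = sum_l A_l e^{j theta_l} x(t - tau_l) exp(j phi_l(t)) + w(t),
    phi_l(t) = 2 pi f_c \int_0^t f_{d,l}(t') dt'.

Doppler profiles are stored *fractionally* (`f_d ~ 2 v / c`, dimensionless),
so the shift in Hz is `f_c * f_d`; time-varying profiles are realized by
phase accumulation, which reduces to a constant shift for constant
velocity. This keeps the echo model dimensionally consistent and lets one
profile serve any carrier.

**Desk-scale conditions.** Simulating 20 MHz of bandwidth is pointless for
the physics under study — the delay axis carries no room-scale information
(range resolution c/2B = 7.5 m even at full scale, and kilometres at
reduced rates) while all of the information is in Doppler, which is set by
the carrier and the motion, both kept at full scale. The bundled scenes
therefore use a 50 kHz IQ rate with a 12.5 kHz-wide source (chip rate
10 kHz). A direct consequence is that the direct signal, the static
multipath background and the subject's echo are all *unresolved in delay*:
they share one range cell and the static part combines into a single
complex channel gain — exactly the regime the full-scale narrowband system
operates in indoors. Scene parameters, chosen once as physically plausible
and fixed:

| quantity | value | rationale |
| --- | --- | --- |
| direct-path amplitude | 1.0 (reference) | normalization |
| static clutter | 0.15, fixed phase | moderate indoor multipath |
| chest echo at 40 cm | 0.14 (−17 dB), 1/d² scaling | strong close-range reflection off the torso |
| body echo | 0.3 (−10 dB) | whole-body cross-section ≫ chest ripple |
| surveillance SNR (direct path) | 40 dB | 30 dBm source at metres from the receiver |
| reference SNR | 50 dB | antenna pointed at the source |
| chest displacement | 5 mm, 12–20 bpm, sinusoid or skewed | resting adult respiration |
| breathing recording | 30 s | matches the evaluation protocol length |
| activity recording | 4 s | one classification window |

**Activity velocity templates** are invented (only spectrogram pictures of
the real activities exist): walking/running are trapezoidal bulk velocities
(1.2 / 2.4 m/s) with sinusoidal gait modulation; jumping is two biphasic
±3.5 m/s bouts (the widest Doppler excursion); standing/sitting are single
short (0.7 s) monotone torso transients of opposite sign; turning is a
short low-amplitude biphasic twist. The corpus generator draws per-subject
systematic speed/gait factors (log-normal, σ = 0.10/0.08) on top of smaller
per-repetition jitter (σ = 0.05/0.04) plus a ±0.2 s timing offset, so
inter-subject transfer is genuinely harder than within-subject splits.

**What the generator does not emulate:** antenna patterns, wall
penetration, carrier frequency offset, IQ imbalance, limb-resolved
micro-Doppler, multiple simultaneous people. Passing tests therefore show
the *processing chain* is correct and robust at realistic SNR; they do not
certify performance on real human recordings.

## 2. Cross-ambiguity processing (`pdsense.radar`)

The batched cross-ambiguity function is evaluated on the grid the batching
construction defines — `n_b` (odd) Doppler bins of width `1/T` centred on
zero, delay bins at the IQ sample spacing — but with the Doppler phase
referenced per sample: for each delay the lag product
`y[n] conj(x[n-d])` is formed once and its DFT is taken at the `n_b`
centred bins (a cached zoom-DFT when `n_b` is small, a full FFT otherwise).
This is an exact factorization of the batched sum at the same asymptotic
cost; the classic "sum within batch, FFT across batches" shortcut is only
an approximation of it (up to ~35 % scalloping loss at band-edge bins) and
is deliberately not used. Tests verify agreement with a literal double-loop
evaluation to better than 1e−6.

Mode defaults: activity `T = 1 s`, span ±60 Hz (121 bins); breathing
`T = 2 s`, span ±1.5 Hz (7 bins). Breathing uses the longer integration
(finer Δf = 1/T) as the two-mode design requires; 2 s stays safely below
half a breathing period, beyond which the per-frame mean Doppler would
integrate to zero. The narrow ±1.5 Hz span is deliberate: chest motion
never leaves the central bins, and outer bins would contribute only
noise — amplified linearly by the micro-Doppler weights below. Frames
overlap (hop 0.25 s, configurable; non-overlapping when `hop_s` is unset)
so the breathing statistic is sampled at 4 Hz, above the 2 Hz belt
reference it is later compared against.

**CLEAN.** The direct path and static clutter put a dominant ridge on the
zero-Doppler line. Each CLEAN pass subtracts the reference's self-ambiguity
surface, scaled by the complex ratio of the zero-Doppler peaks (each at its
own argmax delay) and shifted to align them. The self-ambiguity is computed
over symmetric delays ±max_delay so the full correlation lobe of a direct
path sitting anywhere on the delay axis is cancelled. Iteration (default 4
passes in the pipeline configs, 1 in the bare operation) stops when the
zero-Doppler residual changes by under 0.1 dB, or if a pass would increase
the zero-Doppler line energy (a guard that makes the cancellation
monotone by construction). Greedy subtraction cannot separate heavily
correlated templates at *adjacent* delay bins (sub-chip spacing); this is
immaterial in the unresolved-cell regime above, where the static background
is a single template.

**Spectrogram.** Each frame contributes the magnitude Doppler profile at
the delay bin holding the frame's global |CAF| maximum. Each frame also
records its pre-CLEAN zero-Doppler peak (the direct-path level), carried on
the spectrogram as `direct_levels`.

**Motion indicator.** Per-frame Doppler power sums the squared magnitudes
over all non-zero-Doppler bins (the zero bin is excluded, else the static
residual dominates). The trace is median-smoothed (0.75 s) and thresholded
at 10 % of the waveform amplitude (max − min over a rolling 30 s context)
above the minimum; state runs shorter than 1 s are merged into their
neighbours. A purely relative threshold is ill-posed for a recording
containing a single state, so two absolute anchors are provided: a shared
level calibrated on a pool of traces (one "red line" across measurements),
and the pipeline default — Doppler power relative to the squared
direct-path level, thresholded at 2e−3, the log-midpoint between the
static (≤1.1e−4) and moving (≥3.5e−2) populations of the bundled scenes.
The direct-path normalization makes the threshold dimensionless and
insensitive to overall gain.

## 3. Breathing branch (`pdsense.breathing`)

The chest's peak Doppler (~0.05 Hz at 5 mm, 15 bpm, 915 MHz) is far below
the 0.5 Hz bin, so the spectrogram trace itself stays in the zero-Doppler
bin. The micro-Doppler statistic

    Psi(n) = sum_i D[i, n] * w_i,   w_i = i - (j-1)/2

(odd bin count, weight zero at zero Doppler, positive above, magnitude
growing linearly outward) scores the asymmetry of each frame's Doppler
profile. For a slowly phase-modulated echo the profile is a shifted
Dirichlet kernel and the weighted sum is, to first order, proportional to
the frame's mean Doppler — i.e. chest-wall velocity, positive during
inhale. Psi is linear in the spectrogram, and a profile symmetric about
zero scores exactly zero (this fixes the half-bin ambiguity of the raw
ceil(j/2 − i) ramp for even bin counts: the package always uses an odd
count re-centred on the zero bin).

Psi is smoothed with a Savitzky–Golay filter (window 2 s, polynomial order
3; `scipy.signal.savgol_filter` with polynomial edge handling), which
reproduces any degree ≤ 3 polynomial exactly and preserves peak shape. The
breathing rate is the argmax of the Hann-windowed, 16× zero-padded
magnitude spectrum inside the 6–30 bpm search band; the estimate is flagged
invalid when the series is constant or the in-band peak is below twice the
in-band median (flat spectrum).

**Belt comparison.** Psi tracks velocity while a chest belt reports
displacement (a quarter-period lag for near-sinusoidal breathing), so the
pipeline integrates smoothed Psi (cumulative trapezoid) and removes the
slow trend (10 s centred moving mean) before comparison. The comparator
itself is deliberately plain: resample the radar waveform down to the belt
rate over the overlapping support, normalize the belt to the radar scale,
and report the Pearson R and MSE of the aligned pair.

## 4. Activity branch (`pdsense.activity`)

Spectrograms are cut into non-overlapping 4 s windows (frames grouped by
the interval their centre falls in; every window zero-padded on the right
to a common frame count). Three feature families:

* **SVD** — the leading 10 singular values of the window, descending,
  zero-padded past the rank.
* **PCA** — columns are demeaned per window, the Doppler×Doppler covariance
  is accumulated over *training* windows only, and each window's columns
  are projected onto the leading eigenvectors: the smallest L reaching 90 %
  of the eigenvalue energy, capped at 10. Features are zero-padded to
  `frames × 10` so the length does not depend on the selected L.
* **Physical (6 values)** — active duration (frames with non-zero-Doppler
  power above 10 % of the window peak), Doppler bandwidth (extent of bins
  active above 10 % of the peak magnitude), peak positive and peak negative
  Doppler among active bins, total energy, and the positive/negative
  Doppler energy ratio (softened by 1e−3 of the total energy so one-sided
  signatures stay finite; defined as 1 for an empty window). The exact
  feature list used on the real system was never published beyond the
  named examples (duration, Doppler bandwidth); these six follow those
  examples plus standard micro-Doppler descriptors.

**Classifier.** One-against-one linear soft-margin SVMs
(`sklearn.svm.SVC`, C = 1, kernel and C configurable), one per unordered
class pair — 15 for six classes. Features are z-scored with training-set
statistics. Prediction is majority vote; ties go to the class with the
largest summed signed decision margin. Evaluation protocols: repeated
stratified random splits (default 20 train / 10 test per class × 10
repeats, with an optional accuracy-vs-train-size curve) and
leave-one-subject-out. The PCA basis and the feature standardization are
recomputed inside every split from its training half, so no test
information leaks into the representation.

## 5. Pipeline (`pdsense.pipeline`, `pdsense.cli`)

`run_pipeline` builds the activity-mode spectrogram of the whole recording,
segments it with the motion indicator, then routes static segments through
the breathing branch (re-correlated with the breathing-mode CAF; segments
shorter than 20 s are skipped with a warning — the rate estimator needs two
periods at the band minimum) and moving segments through windowed feature
extraction and, when a model is supplied, classification. Every run
produces a `RunLog` (parameter echo, stage timings, captured warnings,
library versions), and all artifacts are plain CSV/JSON. The `pdsense` CLI
(`simulate`, `process`, `breathe`, `featurize`, `classify`, `run`) is a
thin wrapper; exit codes are 0 (ok), 2 (parameter error), 3 (data error).

## 6. Numerical and degenerate-input choices

* All randomness flows from `numpy.random.SeedSequence` spawning; derived
  integer seeds are kept below 2³¹. Generators are pure functions of
  (spec, seed); the pipeline run on a fixed config and seed is
  byte-reproducible.
* CAF delay bins at exactly the sample spacing; the Doppler axis always has
  an odd bin count so bin 0 is exactly zero Doppler.
* CLEAN on an all-zero self surface returns its input unchanged; an
  all-zero spectrogram yields one static segment; an empty frame list or
  empty window is an error, not a silent empty result.
* The SG window is forced odd and must over-determine the polynomial; the
  pipeline's 2 s window at a 4 Hz frame rate is 9 taps.
* Standardization guards zero-variance features (σ → 1); the PF energy
  ratio is softened as described above.

## 7. Problem sizes

The bundled experiments run on one CPU core: 100 breathing scenes of 30 s
at 50 kHz for rate-recovery statistics, the 180-recording activity corpus
(6 × 10 × 3) for classification, 50 + 50 ten-second traces for motion
discrimination, and 10⁴-sample scenes for the CAF brute-force oracle. These
sizes give stable statistics while keeping a full acceptance run to a few
minutes.

## 8. Known limitations

* The delay axis is exercised only synthetically; bundled scenes live in a
  single unresolved range cell, so range-dependent effects (and CLEAN's
  multi-cell behaviour under sub-chip template correlation) are validated
  in unit tests, not end-to-end.
* Psi's mapping from Doppler asymmetry to chest velocity is first-order;
  strongly non-sinusoidal or very fast breathing bends the waveform (the
  rate estimate is robust to this, the belt R degrades gracefully).
* The motion indicator's absolute anchors assume a stable direct-path
  level; a transmitter with large power swings would need re-calibration.
* Single subject only; overlapping motions (breathing *while* gesturing)
  route to the moving branch and the breathing estimate is simply absent.
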