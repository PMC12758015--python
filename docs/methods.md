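# Methods

`qusmigrate` implements black-box migration of a quantitative-ultrasound (QUS)
tissue classifier from one scanner (the *victim*) to another (the
*perpetrator*), exercised entirely on a built-in RF simulator. This note
documents the model, the synthetic study conditions, and the numerical and
design choices, so results can be interpreted correctly.

## Signal model

Beamformed RF ultrasound admits a multiplicative spectral decomposition

    I(f, x) = S(f, x) · P(f, x),

where `I` is the received spectrum at axial depth `x`, `S` the
machine-and-settings-dependent system response, and `P` the tissue term
(scatterer spectrum plus propagation attenuation). Imaging one calibration
phantom with two machines cancels `P`, so the depth-resolved spectral ratio

    Γ(f, x) = S_victim(f, x) / S_perpetrator(f, x)

maps perpetrator-domain data into the victim's domain: `Γ·X_perp ≈
X_perp→victim`. Because a raw ratio amplifies noise where the perpetrator has
no signal, the applied response is the Wiener form

    Γ_W = |Γ|⁻¹ / (|Γ|⁻² + SNR⁻¹),

with SNR measured per depth window against the noise floor outside the
analysis bandwidth. `Γ_W → |Γ|` as SNR → ∞ and shrinks strictly below `|Γ|`
at finite SNR.

## Migration procedure

1. Acquire paired calibration views (10 stable views by default, or a
   free-hand sweep) and estimate `Γ_W` per depth window.
2. Rate-match perpetrator RF (up-4/down-5 polyphase FIR, 50 → 40 MHz), apply
   `Γ_W`, z-score patches, and query the victim's opaque score interface.
3. Threshold scores with the label-distribution prior: in a balanced binary
   task the median (50th percentile) separates class 0 from class 1.
4. Denoising cycles (iterative learning with noisy labels): re-initialize the
   perpetrator model, train with per-epoch small-loss anchor selection at an
   assumed noise rate ε (anchors = the (1−ε) fraction with the lowest current
   cross-entropy), then re-acquire pseudo-labels from the refined model. A
   fresh 10% validation slice is held out each cycle for monitoring only.
5. Train a final model from scratch on the *raw* (uncalibrated) perpetrator
   patches with the refined labels — the perpetrator-native classifier.

The victim is reachable only through `VictimInterface.query`; nothing else of
the model crosses the boundary (enforced by a static test).

## Synthetic study conditions

The simulator realizes the multiplicative model directly: per lateral line a
Bernoulli–Gaussian scatterer grid is filtered, in 64-sample Hann overlap-add
depth segments, by a zero-phase pulse carrying the segment-center two-way
attenuation `2·acs·depth·f` (dB) and a frequency power-law backscatter
factor abstracting scatterer size; white electronic noise enters at a
configured floor (−40 dB re the shallow in-band peak).

Default profiles:

| quantity | victim | perpetrator |
| --- | --- | --- |
| pulse center | 9 MHz | 5 MHz |
| fractional −6 dB bandwidth | 0.70 | 0.80 |
| sampling rate | 40 MHz | 50 MHz |
| transducer | L9-4-like | L9-4-like (mismatch variant: +1.5 MHz, +20% bw) |

The bandwidths are chosen so the two pulses share a usable band
(≈ 5.5–7.6 MHz); a finite Γ requires spectral overlap. Phantoms: two
classification phantoms with attenuation 0.4 vs 0.1 dB/cm/MHz (backscatter
exponents 0.5 vs 1.5, standing in for 75–90 µm vs 39–43 µm glass beads) and a
0.74 dB/cm/MHz calibration phantom; 30 scatterers/mm² ensures fully developed
speckle. Calibration pairs share one physical scatterer realization drawn on
a 200 MHz common grid and band-limited-decimated to each machine's rate.

Desk scale: frames are 1040 × 128 (half the full 2080 × 256 geometry, ≈ 2 cm
depth), victim data 50 frames/class (80/20 train/validation), perpetrator
24 frames/class (50% held-out test), 16 patches of 200 × 26 samples per
frame, 2 denoising cycles, 5 seeds. The full-scale geometry, 1000
frames/class, and 10 cycles remain configurable; the reduced sizes keep the
whole study reproducible on one CPU in minutes while preserving every
structural element (architecture mismatch, black-box interface, priors).

## Classifiers

The victim and perpetrator default to *different* reduced families — a
concatenative dense-style CNN (victim) vs an identity-skip residual-style CNN
(perpetrator) — retaining the architecture mismatch inherent to a black-box
attack. Networks are small numpy models (a 21 × 3 conv stem with stride
4 × 2, one average pooling, 2 blocks, global average pooling, sigmoid head;
a few thousand parameters) trained with Adam on the patch-wise binary
cross-entropy with 0.5-probability horizontal flips, patches z-scored per
patch. The tall stem matters: 21 axial samples span ~5 periods of a 9 MHz
pulse at 40 MHz, so the first-layer filters can resolve spectral content —
the class cue that survives cross-machine calibration. With a shorter stem
the (very separable) victim task admits solutions based on non-transferable
texture idiosyncrasies, and whether victim scores carry over to calibrated
perpetrator data becomes training-seed roulette. No normalization layers are
used, so evaluation is deterministic by construction. Initialization is
uniform ±1/√fan_in from a per-model seed.

Desk-scale training defaults are lr 3·10⁻³, 20 epochs, batch 64: with only a
few hundred unlabeled patches, larger batches give too few optimizer steps
per denoising cycle and the refined model's ranking direction becomes
seed-random (label inversion). Full-scale protocols (lr 10⁻⁵, batch 2048)
remain available through `TrainConfig`.

## Numerical and design choices

- **Γ estimation**: view- and line-averaged Hann-tapered periodograms per
  200-sample depth window (50% overlap); ratio of averaged power spectra,
  then square root — lower variance than averaging per-view amplitude
  ratios. Γ is magnitude-only; the input's phase (which carries the tissue
  term) is preserved during application.
- **Analysis band**: bins where both machines' calibration spectra sit within
  20 dB of their in-band peak (contiguous run around the joint peak). The
  noise floor is measured above 1.2× the upper band edge; per-window SNR is
  capped at 10⁶ so noiseless data stays finite.
- **Out-of-band handling**: the raw ratio is clamped to its band-edge value,
  Wiener-shrunk, and then rolled off to zero with an 8-bin raised cosine
  beyond the band. Without the rolloff the clamped ratio multiplies pure
  perpetrator noise into the calibrated output, which at desk scale is strong
  enough to invert the victim's decisions; rolling off accepts that the
  victim's upper band simply cannot be synthesized from perpetrator data.
- **Application**: zero-phase magnitude filtering via Hann overlap-add with
  reflection padding (exact identity reconstruction when Γ_W ≡ 1); patches no
  taller than one depth window are filtered as a single rectangular window at
  their recorded frame depth, with Γ_W linearly interpolated between depth
  centers.
- **Anchor selection**: per-epoch, from a no-update loss pass, within each
  pseudo-class. Global selection (the printed rule) is available via
  `per_class_anchors=False`, but with from-scratch reduced networks it admits
  a feedback loop — an initially one-sided model keeps its own majority class
  as anchors — that calibrates the ranking but not the 0.5 threshold;
  per-class selection keeps the anchor set balanced.
- **Ties and rounding**: pseudo-labeling assigns exactly ⌊n·p/100⌋ zeros with
  stable-sort tie-breaking by index; anchor counts are round((1−ε)·n);
  frame splits are class-stratified with largest-remainder rounding and
  rounding debt carried across classes.
- **Final training**: from scratch on raw patches with the same anchor-gated
  protocol (the refined labels are still noisy); fine-tuning the cycle model
  instead is exposed as `fine_tune_final`.
- **Determinism**: every output is a pure function of profiles and integer
  seeds (numpy `SeedSequence` children); model training is exactly
  reproducible on a fixed BLAS configuration.

## What the simulator does and does not capture

It reproduces the features the method depends on: machine-specific band
placement, depth-dependent spectral attenuation contrast between classes,
shared calibration realizations, sampling-rate mismatch, and electronic noise
floors. It does not model lateral beam formation or element directivity
(frames are emitted as beamformed RF, lines independent), speed-of-sound
aberration, nonlinear propagation, or reverberation clutter. Consequently the
synthetic task is cleaner than the real one: the victim reaches ~100%
validation accuracy and migrated accuracies saturate near 100%, so passing
tests demonstrate the machinery (calibration, black-box labeling, denoising)
rather than clinical-grade difficulty, and the harness asserts *orderings*
(calibrated beats uncalibrated; robustness bands) rather than absolute
real-data scores.

## Known limitations

- Balanced binary classification only; the percentile prior assumes the
  class mix is known.
- Γ covers only the joint analysis band; content in the victim's exclusive
  band is irrecoverable and is deliberately suppressed.
- The noise-rate ε is a prior, not estimated from data.
- Free-hand calibration uses lateral translation jitter (uniform 0–2 mm) as
  its decorrelation model.
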