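# Methods

## The measurement model

`limbtherm` quantifies bilateral skin-temperature asymmetry of the lower
limbs from radiometric thermal video. The subject's healthy leg is the
internal reference: for an ROI on the affected leg with across-frame mean
temperature `T_a` and its mirrored counterpart `T_h`, the statistic is

```
pct_diff = (T_a − T_h) / T_a × 100        [%]
```

All temperatures are °C end to end; Kelvin appears only in noise
magnitudes (1 mK = 0.001 °C difference). The denominator is the affected
side, so swapping the roles of the two ROIs does not simply negate the
value — it flips the sign and rescales by `T_a / T_h`. `pct_diff` is
computed and stored at full float precision; rounding to 2 decimal places
happens only when tables are formatted.

The averaging order is: pixel mean within the ROI per frame, then the
unweighted mean of those per-frame means over the selected frames, for the
affected and healthy ROIs over the *same* frame set. Pixel values are
averaged as temperatures, not as radiometric counts.

## Frame selection

Clinical recordings contain frames where the subject moved. Each frame is
scored by the centred (Pearson) correlation between the frame and the
pixelwise median frame of the recording; the median reference is robust so
long as corrupted frames are a minority. The K highest-scoring frames are
kept (default K = 20, the count used in the clinical protocol this
pipeline automates), ties broken toward the earlier frame for determinism.
Conventions for degenerate inputs: a single-frame recording scores 1; a
zero-variance frame scores 0. One selection is made per recording and
shared by all five ROIs — the alternative (re-selecting per ROI) is not
supported, because nothing in the measurement model depends on the ROI
once the subject holds still.

If a recording holds fewer than K frames, all frames are used and a
warning is issued rather than an error — short recordings are common in
paediatric practice and still carry signal.

## ROI geometry

ROIs are 0-based half-open rectangles `[top_left, bottom_right)`. The
half-open convention makes width/height arithmetic exact and makes the
mirror operation an involution: column range `[s, e)` maps to
`[W − e, W − s)` about the default axis `W/2`. An explicit axis column can
override the default (for subjects not centred in the frame); the
reflected range must land on the pixel grid and inside the image. ROI
sizes are user-chosen per subject (larger legs warrant larger ROIs); the
package validates but does not auto-size them, except in synthetic mode
where sizes derive from the phantom geometry.

## Exclusions and region relevance

Subjects are excluded when symptom onset exceeded 48 h (skin temperature
normalises), at age 15 or over, with bilateral involvement (no internal
reference remains), or without an established diagnosis. Exclusions carry
machine-readable reason codes and excluded subjects are reported, never
silently dropped.

Because resting skin temperature falls proximodistally along the leg,
different ROIs cannot be compared with each other; only the ROIs over the
presenting-complaint region enter group analysis: hip/thigh → hip and
upper-knee; knee → knee; lower leg → lower-knee; ankle → ankle.

## Group summaries

Subgroup sample sizes are small and skewed, so groups are summarised by
medians with IQRs, computed across subjects separately for the affected
and healthy means. The group percentage difference applies the asymmetry
statistic to the two group medians — not the median of per-subject
percentages. This convention is fixed deliberately: it regenerates every
published group percentage exactly (2 dp) from the published medians,
which the median-of-percentages convention cannot be verified to do.
Quartiles use linear interpolation between order statistics (the common
default; the original study's quartile method is unverifiable because
per-subject data were never published, and no reported quantity here
depends on the IQR). Single-subject groups report the median and an absent
(`n/a`) IQR. Subjects with diagnoses outside the three named groups
(soft-tissue injury, irritable hip, fracture) are retained by the
exclusion step and appear in descriptive tables, but have no group-summary
row. A subject lacking a recording in some position contributes nothing to
that position's rows, so `n` may vary across rows.

## The synthetic phantom

The phantom emulates the imaging subject, not limb biophysics:

- **Geometry** — two vertical leg silhouettes with linearly tapering
  half-width, specified fractionally so the same scene renders at any
  resolution. The right leg is the exact `fliplr` mirror of the left, so
  with zero noise and no hotspot every mirrored ROI pair has *exactly*
  equal means — the null-symmetry identity the tests exploit.
- **Temperature** — a linear proximodistal gradient (default 33.5 °C at
  the top of the leg to 30.5 °C at the ankle) over a room-temperature
  background (23 °C).
- **Pathology** — an additive isotropic Gaussian hotspot on the affected
  leg, the simplest localised elevation with an analytically/numerically
  integrable ROI mean (the oracle used in tests). Amplitude is the
  per-subject `ΔT`; sigma defaults to 0.4 × ROI height.
- **Sensor noise** — i.i.d. per-pixel Gaussian noise, SD 0.04 °C, the
  NETD of the 640 × 480 microbolometer camera the protocol specifies. The
  camera's −40…650 °C operating range bounds all valid temperatures.
- **Motion corruption** — a seeded fraction of frames is rendered from a
  horizontally shifted scene (8% of image width, minimum 4 px) with a
  +2 °C bias on the shifted limb pixels. Corruption is visible only in
  frame content, so frame selection must detect it.

Single recordings default to the clinical acquisition geometry: 20 s at
30 Hz (600 frames) at 480 × 640. Cohort simulation uses reduced defaults
(1 s at 30 Hz, 120 × 160) because a full-geometry cohort is tens of
gigabytes of rasters and adds nothing statistically — per-ROI means
converge with a handful of frames at these noise levels.

### Cohort model

Each diagnosis group has a size, a hotspot-magnitude distribution
`ΔT ~ N(mean, sd)` truncated at 0, and a distribution over complaint
regions. Defaults follow the pilot-study cohort structure (13 soft-tissue
injuries, 9 irritable hips, 3 fractures, 4 other, 1 undiagnosed) with
`ΔT` means ordered fracture (2.5 °C) > soft-tissue injury (1.2 °C) >
irritable hip (0.4 °C), calibrated once so the resulting group percentage
differences land in the observed 0.7–5.3% range. These magnitudes are
artifact choices — the study published no hotspot amplitudes — and are
labelled as such. Each subject additionally draws a whole-leg baseline
shift (SD 0.8 °C), giving group IQRs of realistic magnitude; without it
all simulated subjects share one baseline and healthy-side IQRs collapse
to ≈ 0, which no real cohort shows.

The hotspot is centred under the *primary* ROI of the subject's complaint
region (hip/thigh → hip, knee → knee, lower leg → lower-knee, ankle →
ankle). For the hip/thigh region, which maps to two relevant ROIs, this
means the upper-knee ROI sees almost none of the elevation — hence the
parameter-recovery statistic reads each subject's primary ROI. Synthetic
subjects are recorded in the anterior sitting and anterior standing
positions; the hip ROI is read from the anterior view in synthetic mode
(clinically the hip is imaged laterally because of underwear artefacts,
which the phantom does not model).

All randomness flows through one seeded `numpy` generator passed
explicitly; identical seeds give bit-identical cohorts, recordings and
pipeline outputs.

### What the synthetic validation shows — and does not

Passing tests establish that the pipeline's arithmetic is correct (oracle
equivalence), that its null behaviour matches theory (the noise-only
asymmetry stays within `3·(σ√2/√(N·F))/T̄ × 100` in ≥ 99% of trials),
that frame selection reliably removes the modelled corruption, and that
configured group orderings are recovered from simulated cohorts. They do
*not* show that the method separates diagnoses in real children: the
phantom has no perfusion physiology, no clothing or underwear artefacts,
no pose variability beyond rigid shift, and its hotspot amplitudes are
assumptions. The published absolute median temperatures and IQRs are used
only as realistic ranges, never as recoverable targets.

## Numerical choices

- tiff16 storage quantises at 0.01 K/count — strictly finer than the
  40 mK NETD, so storage never dominates sensor noise; round-trip error is
  bounded by half a step (0.005 K). CSV rasters print at 0.1 mK.
- Frame count is `floor(duration × rate)` with a 1e-9 guard against float
  products like `0.3 × 30 = 8.999…`.
- Score ties in frame selection break toward the earlier frame; group
  summary rows are emitted in sorted (region, ROI, position, diagnosis)
  order; both choices exist only for determinism.
- Validation rejects: non-finite or out-of-range temperatures, empty or
  ragged rasters, non-consecutive frame indices, decreasing timestamps,
  degenerate rectangles, out-of-bounds ROIs (including mirrored ones under
  an off-centre axis), empty frame-index lists, `k < 1`, empty groups and
  empty cohorts, and a non-positive asymmetry denominator.

## Problem sizes used in the validation suite

Tests and simulations run on reduced rasters (24 × 32 up to 96 × 128) and
short recordings; the statistics under test are resolution-independent
(means, medians, correlations), so nothing is lost relative to full
640 × 480 frames. The replicate parameter-recovery study uses 100 seeded
25-subject cohorts (12 soft-tissue / 8 irritable-hip / 5 fracture) at
72 × 96 with 30 frames per recording and K = 20, and requires the
configured ordering to be recovered in ≥ 95 of 100 replicates.

## Known limitations

- The quality score detects global geometric/thermal deviation, not the
  specific "image angle" judgement a human selector applies; subtle pose
  changes that preserve correlation pass unnoticed.
- The mirror rule assumes the subject is framed symmetrically about the
  image midline (or that the caller supplies the axis); it does not
  estimate the axis from the data.
- Automatic lesion localisation is out of scope: ROIs are inputs.
- No hypothesis testing or sensitivity/specificity estimation is provided;
  at the pilot's sample sizes such tests would be uninformative, and the
  upstream study performed none.
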