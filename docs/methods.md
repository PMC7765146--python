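# Methods

This note documents the models and numerical conventions behind
`meowdecode`, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Acoustic analysis

All analysis assumes mono PCM audio at 8 kHz (other input is downmixed
and polyphase-resampled with a warning). Frames are 32 ms (256 samples)
with a 10 ms (80-sample) hop and a Hann window — at least two periods of
a 100 Hz pitch floor — and the STFT uses no padding or centering, so a
clip of `n` samples yields `floor((n − 256)/80) + 1` frames.

### Pitch

F0 is estimated per frame by a SWIPE′-style kernel correlation. The
square-root-compressed magnitude spectrum (zero-padded FFT, 2048 points)
is correlated against a bank of sawtooth-spectrum kernels on a log-spaced
pitch grid (1/48 octave, 75–1800 Hz by default): the kernel for candidate
pitch `p` has cosine lobes at the first and the **prime** harmonics of
`p`, half-weight troughs on the lobe shoulders, and a `1/√harmonic`
decay. Restricting lobes to prime harmonics is what suppresses
subharmonic errors — a candidate at `f0/3` collects credit from only one
of the true harmonics instead of every third lobe. (An earlier continuous
cosine kernel exhibited exactly these `f0/3` errors on synthetic meows;
the prime-lobe kernel removed them.)

The normalized correlation (kernel norm × norm of the spectrum over the
kernel's support), clipped to [0, 1], is the confidence score. Frames
with confidence ≥ 0.15 are voiced; the comparison is inclusive.
Silence yields zero confidence rather than an error. The winning grid
candidate is refined by parabolic interpolation on the log-pitch axis.

Pitch analysis uses a longer 64 ms window than the spectral features,
zero-padded at the clip edges so pitch frames stay centered on the same
frame grid. The longer window sharpens the harmonic kernels and keeps
the maximal correlation of unpitched (noise) frames comfortably below
the 0.15 voicing floor; on white noise ≥ 95 % of frames score below it,
while harmonic tones score ≈ 0.5.

### Roughness

Per frame, spectral peaks are local maxima above −60 dB of the frame
maximum, capped at the 20 largest (bounding the quadratic pair cost; an
8 kHz band-limited harmonic signal rarely has more). Every unordered
peak pair (f₁,a₁), (f₂,a₂) contributes

    (a₁a₂)^0.1 · 0.5 · (2·min(a₁,a₂)/(a₁+a₂))^3.11 · (e^(−b₁sΔf) − e^(−b₂sΔf)),
    s = s* / (s₁·min(f₁,f₂) + s₂)

with b₁ = 3.5, b₂ = 5.75, s* = 0.24, s₁ = 0.0207, s₂ = 18.96 — the
partial-pair (critical-band interaction) model of Vassilakis. The
contribution peaks when partials sit tens of Hz apart in the vocal range
and vanishes for distant partials; amplitude dependence is deliberate
(total roughness of an equal pair scales as `a^0.2`), so roughness is
the one feature not invariant to recording gain. Fewer than two peaks
give zero. Roughness needs no pitch, so it is aggregated over all
frames, voiced or not.

### Tristimulus

Harmonic k's energy is the summed squared magnitude in a band around
`k·f0`. The band half-width is ±3 % of `k·f0`, **floored at two bin
widths** (the Hann window's resolution limit, 62.5 Hz at the default
framing) and capped at `f0/2` so neighbouring harmonic bands never
overlap. Without the floor, a ±3 % band at meow pitches would be
narrower than a harmonic's own spectral main lobe and even a pure tone
would not yield T1 ≈ 1. T1 is the fundamental's fraction, T2 the
fraction of harmonics 2–4, T3 of all higher harmonics; the denominator
is the frame's total spectral energy, so T1+T2+T3 ≤ 1 and inharmonic
energy only dilutes. Zero-energy frames are dropped. Tristimulus is
undefined without a pitch, so T statistics (like F0's) run over voiced
frames only.

### Aggregation

Each recording reduces to ten values: mean and sample SD (ddof = 1) of
F0, R, T1, T2, T3. "SD" was chosen over a min–max range statistic as the
reading of a per-recording dispersion summary; it is the conventional
second moment and yields exactly the intended 10-value space. A
recording with fewer than two usable voiced frames is flagged unusable
rather than silently summarized.

## Screening and exemplar selection

Each of the 10 columns is screened independently by a classic one-way
ANOVA across context labels (no Welch correction, no multiple-testing
adjustment — the screen is deliberately per-column at α = 0.05, with a
per-family summary reported alongside). A column constant everywhere has
an undefined F and is dropped with a warning.

Hz, roughness units and energy ratios are incommensurate, so features
are z-scored over all recordings before centroids and Euclidean
distances are computed; `standardize=False` reproduces raw-space
behaviour (whether the original analysis standardized is unknowable from
the outside, so both modes exist and the mode is recorded). Medioid =
argmin distance to own class centroid, outlier = argmax, ties broken by
lowest clip id; classes need ≥ 2 members so the two roles are distinct
recordings.

## Survey scoring and statistics

AES: 22 nine-point items, 11 empathic + 11 unempathic; unempathic items
are reversed (10 − x, an involution) before summing, giving totals in
[22, 198] with 110 the all-neutral fixed point. The real instrument's
reverse-scoring key is not public here; the package default is a
synthetic alternating key, and any 11/11 key can be supplied. CES: plain
sum of 3 nine-point items, [3, 27].

Chi-square tests are Pearson on the classical expected counts, with the
Yates continuity correction **off by default** (flag available);
contingency cells asserted in the tests are those whose published
significance bound holds under both conventions. The chance-level test
is an exact binomial against p₀ = 1/3 (both one-sided-greater and
two-sided p reported; "chance = 0.33 %" in the source tables is read as
the proportion 1/3). Mann–Whitney switches from the exact null
distribution to the tie-corrected normal approximation above 20
observations per group or in the presence of ties; the method used is
recorded. Cronbach's α uses the standard item-variance formula with
sample variances. The 0–3 "correct identifications" score counts medioid
presentations only — its range forces that reading. Records missing an
answer are excluded from the specific analysis only.

## Descriptor PCA

One observation = one participant × one meow (11 descriptor scores);
subsetting to correctly classified responses is therefore per
assignment, not per participant. Default mode is correlation-matrix PCA
(descriptors standardized); covariance mode is available and the mode is
recorded in the output. All 11 components are kept, so explained
variance sums to 100 %. Signs are fixed deterministically: PC1 is
oriented so the calm/relaxed loading is ≤ 0 (negative PC1 = positive
valence), the other components so their largest-magnitude loading is
positive. At least 12 observations are required.

## Synthetic generators

`synth_meow` renders additive harmonics on a linear F0 contour
(truncated below the 4 kHz Nyquist limit), with per-octave rolloff
(default 9 dB/oct), a sinusoidal AM envelope normalized as
`(1 + d·sin 2πf_am t)/(1 + d)` so that peak amplitude — and with it
overall energy — stays comparable while modulation depth (and hence
roughness) varies, a 10 ms raised-cosine fade at each end, and Gaussian
noise at a target SNR (default 25 dB). Default AM rate is 100 Hz, inside
the maximal-roughness region for kHz-range carriers and wide enough to
be resolved as sidebands by the 32 ms analysis window. All draws come
from one seeded generator per call.

`synth_corpus` draws per-context parameters from stated distributions.
The default three contexts are plausibility choices, not calibrated to
any recorded corpus (no per-context acoustic ranges are published for
the breed in question): food solicitation 600→700 Hz rising with light
AM, isolation 520→380 Hz falling with strong AM (distress roughness),
brushing 340→420 Hz gently rising and nearly unmodulated — following the
general observation that positive contexts tend to rising contours and
negative ones to falling contours.

`synth_cohort` emulates a 225-respondent online survey: Bernoulli
attributes at the study's observed rates (65 % female, 48 % cat owners);
classification accuracy keyed by (ownership group, context), with owners
more accurate, errors uniform over the two wrong contexts (no confusion
structure is published), and an outlier recognized at 0.55× the medioid
rate of its context (the published outlier/medioid accuracy ratios range
0.41–0.67); empathy items drawn around group means on the item scale
with a shared latent trait (SD 0.6) plus item noise (SD 1.5) — the trait
induces the positive inter-item correlation that produces a realistic
Cronbach's α near 0.8 and the AES–CES correlation; unempathic items are
stored on the reversed scale. Descriptor ratings follow a single latent
valence factor: `round(4 + 3·v·sign(descriptor) + N(0, 1))` clipped to
1..7, with planted context valences +0.8 (brushing), +0.3 (food), −0.8
(isolation). A one-factor model was chosen because the target analysis
reads one dominant valence axis from PC1.

What the generators do **not** emulate: real vocal-tract acoustics
(formants are deliberately out of scope — with few harmonics in a
band-limited signal they are unreliable anyway), within-cat repertoire
structure, inter-rater descriptor correlations beyond the single valence
factor, or response styles (acquiescence, central tendency). Passing
tests therefore demonstrate that the chain recovers structure *of the
kind assumed*, not that real meows or respondents have that structure.
In particular, the published PCA variance percentages and
empathy–accuracy correlations depend on the study's raw responses and
are not reproducible from synthetic cohorts; the test surface is
parameter recovery (planted valence |r| > 0.9, context ordering, loading
sign partition), plus the published count tables, which *are*
reproducible exactly and are bundled in `meowdecode.datasets`.

## Problem sizes and calibration checks

The ANOVA screen's type-I calibration (rejection rate within 3 standard
errors of α over 500 null replicates) runs on directly generated
Gaussian feature tables — the screen consumes feature tables, so this is
the natural calibration surface; the audio path is exercised separately
by a 100-corpus simulation with well-separated per-context F0 means
(300/500/700 Hz, SD 20 Hz), which the screen must keep in ≥ 95 % of
runs. Exemplar selection is checked against an exhaustive-search oracle
on 100 random datasets (3 classes × up to 50 points × up to 10
features). Pitch recovery uses 50 synthetic meows with F0 ∈ [250, 700]
Hz (median F0-mean error < 3 %; measured ≈ 0.2 %). The demo pipeline
uses 6 clips per class and 120 respondents.

## Known limitations

- The pitch tracker is designed for clean harmonic vocalizations; heavy
  broadband noise lowers confidence rather than producing robust
  tracking, and no temporal continuity (Viterbi-style) smoothing is
  applied.
- Roughness depends on peak picking; two partials closer than the
  window's resolution merge and contribute nothing (AM rates well below
  ~60 Hz at the default framing are invisible to it).
- Chi-square p-values near a printed significance boundary can cross it
  depending on the correction convention; both conventions are exposed
  and the default (uncorrected) is recorded in every result.
- The synthetic cohort's accuracy map uses ownership as the only
  accuracy-relevant grouping; gender affects empathy but not accuracy in
  the generator, so gender×accuracy tables on synthetic cohorts are null
  by construction.
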