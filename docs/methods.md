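# Methods

## The measurement model

Phase-contrast CMR encodes through-plane velocity into pixel phase; summing
velocity over a vessel's cross-section gives instantaneous flow, and an
ECG-gated acquisition resolves one averaged cardiac cycle into `n` frames
(default 35, frame duration `rr/35` ≈ 25–30 ms). Flow samples are treated as
frame means, nominally centred at `(i + 0.5)·Δt`.

All volumes derive from the rectangle rule — net flow per beat is
`Σ flow_i · Δt` — not the trapezoid rule, so that hand arithmetic on printed
flow values matches the implementation exactly. For a sinusoidal
arterio-venous imbalance the cumulative rectangle sum converges to the
analytic volume curve with relative error ~7·10⁻⁴ at 35 frames, far below the
other error sources.

The pulmonary blood volume variation (PBVV) is the range (max − min) of the
running sum of per-frame net in/outflow `(Q_arterial − ΣQ_venous)·Δt`. It is
computed independently per scope: right lung (RPA vs right veins), left lung,
and bilaterally from the summed curves — the bilateral value is *not* the sum
of the unilateral values, since the lungs' volume curves need not peak in the
same frames (the range of a sum is bounded by the sum of ranges, an invariant
the tests assert). The cumulative curve starts at the first frame's
differential; no zero-anchoring is applied. The choice is cosmetic: PBVV is
translation-invariant, which is also asserted.

No drift correction is applied by default — the arterio-venous mismatch per
cycle is reported, not removed, so measurement inconsistencies stay visible.
An optional linear-drift-removal flag (`drift_correction`) closes the
cumulative curve at zero for callers who want it.

Relative PBVV is PBVV indexed to the ipsilateral arterial net flow per beat,
in percent. The pulmonary vascular distensibility reserve (PVDR) is the
percent change in unilateral relative PBVV between two body positions; the
supine position is the reference unless the caller specifies otherwise. All
percentages are carried on the 0–100 scale.

## Image-space quantification

**Eddy-current correction.** Uncompensated eddy currents add a slowly varying
spurious phase offset, modelled as a spatial quadratic
`a + b·x + c·y + d·x² + e·x·y + f·y²` (cm/s, pixel coordinates, x = column,
y = row, pixel centres at integer coordinates). The surface is least-squares
fitted to the *time-averaged* velocity of static-tissue pixels — the offsets
are temporally static, so averaging over frames suppresses noise — and
subtracted from every frame; per-frame fitting is available behind a flag.
At least 30 static pixels are required and a rank-deficient design (e.g.
collinear pixels) is refused. On noiseless data recovery of an injected
surface is exact to numerical precision; with 1 cm/s velocity noise and a few
hundred static pixels the *surface* is recovered to a few percent of its
range, although the three second-order coefficients are individually noise
dominated (their magnitudes, ~10⁻³ cm/s/px², sit below the attainable
standard errors at realistic pixel/frame budgets).

For real data a static-tissue mask can be built from pixels with low temporal
velocity SD and above-noise-floor magnitude (`quant.static_tissue_mask`);
synthetic data ship exact masks.

**ROI propagation.** The acquisition protocol delineates each vessel once and
propagates the contour automatically. Here propagation is: per frame, Otsu
threshold on the magnitude image, take the 4-connected bright component
containing the previous frame's mask centroid, then morphological closing and
hole-filling. Losing the vessel raises an error naming the frame. A fixed-ROI
mode (reusing the initial mask) serves plug-profile tests. On synthetic
pulsatile vessels at 1.4 mm pixels the per-frame area tracks truth within
~15%, dominated by pixelation of small venous lumens.

**Flow and area.** ROI flow is `Σ velocity · pixel_area` converted to ml/s
(1 cm/s over 1 mm² = 0.01 ml/s); area is pixel count × pixel area, averaged
over the cycle.

## The synthetic generator

The generator emulates the study conditions: healthy adults imaged in four
body positions at 35 frames/cycle, seven vessels per position.

**Waveforms.** Closed-form waveform shapes are not part of the measurement
protocol, so the generator uses sums of asymmetric Gaussian pulses: the
arterial curve is a single skewed systolic pulse (peak at ~17% of the cycle)
with a small end-systolic notch; the venous template has a systolic S wave,
a dominant diastolic D wave and a negative A-wave reversal straddling the
cycle boundary. The rectangle-rule integral is normalized to the requested
stroke volume exactly.

**Venous construction.** Given an arterial curve and a target PBVV, the
summed venous flow is `Q_v = (1−β)·Q_a + β·template` with the template scaled
to the arterial net flow and β chosen so the implied volume curve has range
exactly equal to the target. Conservation (venous net = arterial net) and
PBVV recovery are then exact by construction; a zero target degenerates to
venous ≡ arterial. Targets that would force venous backflow deeper than 15%
of the arterial peak on more than 20% of frames are refused as infeasible,
and cohort generation clamps per-lung relative-PBVV targets at 1.05 for the
same reason (mirroring the velocity-encoding clamp below).

**Image rendering.** The vessel is a centred circular lumen with a parabolic
(Poiseuille) velocity profile whose ROI integral equals the curve's flow;
each pixel's velocity is the mean over a 5×5 subpixel grid, so the
discretization error of the ROI integral is ≲1% at 1.4 mm pixels for
arterial-sized lumens. A uniform plug profile is available for analytically
exact tests. The quadratic eddy surface and Gaussian velocity noise are added
on top; the magnitude image is bright inside the lumen (partial-volume
shaded). If the implied centreline velocity exceeds the velocity-encoding
limit, generation refuses — phase wrapping is deliberately never simulated,
and the pipeline's own renderer raises the encoding limit instead (a
parabolic profile doubles the mean velocity, which clinical plug-like flow
does not).

**Cohorts.** Default calibration reflects the healthy supine condition:
stroke volume 106 ml, heart rate 61 bpm, right flow fraction 0.52, supine
relative PBVV 0.47 (right lung) and 0.39 (left lung) — i.e. lung PBVVs of
about 26 and 20 ml and a bilateral PBVV near 46 ml. Positional effects are
multiplicative gains applied in the lateral positions only: the dependent
lung's flow fraction gains 25% (the non-dependent lung absorbs the
complement, so cardiac output is position-independent by construction, up to
position-level noise), dependent venous areas gain 25%, and the non-dependent
lung's relative PBVV gains 90%. Between-subject variability is log-normal
(CV 0.15 on stroke volume and relative PBVV, 0.12 on heart rate, 0.20 on
gains; SD 0.02 on the flow fraction), and within-subject position-level
noise is small (CV 0.03 on stroke volume and heart rate, 0.08 on relative
PBVV). Each lung's venous pair is derived from that lung's arterial curve, so
conservation holds per lung exactly; the four veins split each lung's venous
flow 50/50 superior/inferior (no superior/inferior asymmetry is imposed,
matching the absence of a measured one). Optional additive white noise
(default 1.0 ml/s, ~1–2% of the arterial peak) emulates post-ROI curve noise.
Everything is reproducible bit-for-bit from the seed via spawned substreams.

What the generator does **not** emulate: respirophasic flow variation
(averaged away by multi-excitation acquisition in practice), beat-to-beat
variability or arrhythmia, velocity aliasing, partial-volume and misalignment
errors of oblique imaging planes, inter-vessel timing offsets, or anatomical
variants (e.g. accessory veins). Passing tests therefore demonstrate the
correctness and calibration behaviour of the *analysis*, not the accuracy of
the acquisition itself on real scanners.

## Statistics

Continuous summaries are mean ± SEM (sample SD with `n−1`, divided by √n).
Paired comparisons use the Wilcoxon signed-rank test: zero differences are
discarded before ranking (classic Wilcoxon rather than Pratt), tied absolute
differences receive mid-ranks, the null distribution is exact for up to 25
non-zero pairs (subset-sum dynamic programming over doubled mid-ranks, so
ties stay inside the exact path), and a normal approximation with continuity
and tie correction is used above. Two-group comparisons use the Mann-Whitney
U test, exact for combined n ≤ 20 by the analogous labeling enumeration.
Two-sided p-values are defined as the null probability of a statistic at
least as far from its mean as observed, which coincides with the usual
doubled one-sided tail for these symmetric null distributions. Repeated
measures across the four positions use the Friedman test (mid-ranks,
chi-square approximation, via scipy). No multiple-testing correction is
applied — a deliberate mirror of small-cohort physiology practice and a known
limitation.

Interobserver agreement between two readers of the same raw data reports the
mean and SD of unsigned percent differences from the pair average, the
Dahlberg error `√(Σd²/2n)`, the relative Dahlberg error (percent of the
grand mean), and the intraclass correlation coefficient. The ICC variant is
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
the standard choice for two raters scoring the same subjects; other variants
are selectable. ICC(2,1) is invariant under a common shift of both observers
but not under rescaling (asserted in the tests); the computation delegates to
pingouin and returns NaN when fewer than three subjects make the underlying
ANOVA undefined.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's native scale: cohorts of
10 subjects × 4 positions × 7 vessels at 35 frames; type-I-error and power
checks use 500 and 100 seeded replicate cohorts respectively — sizes at which
the Monte-Carlo bands quoted in the tests are meaningful. Exact-test oracles
enumerate up to 2⁸ sign patterns and C(10,5) labelings. Float64 throughout;
curve equality tolerances are stated per test (conservation to 0.1% of stroke
volume, noiseless recovery to one frame-volume, i.e. the largest single-frame
volume increment). Degenerate inputs (zero stroke volume, zero PBVV target,
all-tied statistics) are covered by explicit contracts rather than silent
fallbacks.

## Known limitations

* ROI propagation is intensity-based and will fail on low-contrast magnitude
  images; the failure is loud (frame-numbered error), not graceful.
* The venous waveform family is a two-parameter mixture; it cannot represent
  pathological venous flow patterns (systolic blunting, deep A reversal of
  elevated atrial pressure).
* Relative PBVV targets above ~105% of net flow are not constructible without
  implausible backflow and are clamped in cohort generation.
* The quadratic eddy model matches the correction convention it emulates;
  higher-order or temporally varying offsets are out of scope.
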