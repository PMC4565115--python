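# Methods

## What the pipeline measures

`flyheart` quantifies *Drosophila* heart function from M-mode optical
coherence microscopy (OCM) recordings: repeated 2-D cross-sections of the
heart tube acquired at a fixed position (default 128 Hz, sessions of
~30 s).  The heart-chamber lumen appears as a dark ellipse inside a bright
wall; its cross-sectional area over time is the carrier signal for every
derived quantity:

- **EDD/ESD** — end-diastolic/end-systolic diameter, per axis (horizontal
  = transverse x, vertical = axial z), measured as the full axis-aligned
  extent of the lumen mask.
- **EDA/ESA** — end-diastolic/end-systolic lumen area.
- **FS** — fractional shortening, `FS = (EDD − ESD)/EDD × 100`, computed
  per axis and for area.
- **HR** — heart rate (bpm) from diastole-to-diastole intervals, using
  only the time the heart actually beats.
- **CAP** — cardiac activity period: the percentage of the session during
  which the heart beats.  The pupal fly heart starts and stops; CAP is the
  duty cycle of that behaviour.  Example: 4.8 s of rest followed by 7.6 s
  of beating gives CAP = 7.6/12.4 = 61%.
- **CDD** — cardiac developmental diastasis: the contiguous beatless span
  during pupa day 2 while the chamber is rebuilt, scored from the 8-hourly
  sampling grid as (length of the longest beatless run of pupal time
  points) × 8 h.  A fully beatless pupal series cannot be bounded and is
  flagged death-censored.

Per time point, five recordings are averaged (CAP and all parameters,
arithmetic mean); groups are compared per stage with an unpaired
two-tailed pooled-variance Student's t-test (Welch behind a flag), raw
p-values, stars at 0.05/0.01/0.001.  Survival to adulthood is plain
fraction arithmetic reported as an integer percent.

## Segmentation (magic wand)

Per frame: optional 3×3 median pre-filter, then a 4-connected flood fill
from a seed pixel with an absolute intensity tolerance, hole filling
(speckle voids inside the lumen otherwise fragment the mask), and
selection of the component containing the seed.  Choices worth noting:

- **4-connectivity** avoids diagonal leaks through the one-to-two-pixel
  heart wall.
- **Absolute tolerance** around the seed intensity; the default is half
  the estimated lumen-to-wall separation of frame 0.  Levels are read off
  percentiles — lumen = 5th percentile of the central window, tissue =
  frame median, wall = 98th percentile — because the frame histogram has
  three modes with very unequal weights (tissue ≫ lumen ≈ wall) and a
  two-class split such as Otsu's can land inside the tissue mode.
- **Runaway guard**: a mask touching more than 25% of the image border
  means the fill escaped the lumen; the frame is flagged failed, never
  interpolated.  More than 50% failed frames aborts the series.
- **Tracking**: frame k is seeded at the centroid of frame k−1's mask,
  falling back to the initial (auto or user) seed.  The auto seed is the
  centroid of the largest dark blob (≤ 10th percentile) in the central
  quarter of frame 0.
- A fill is accepted only if its mean intensity is darker than halfway
  between the lumen and tissue estimates, so a seed that lands on tissue
  is rejected instead of producing a plausible-looking wrong mask.

Diameters are full extents ((max − min + 1) pixels × pitch), matching the
horizontal/vertical naming of the parameters, not centroid chords.

## Beat detection and parameters

The area trace is smoothed with a 5-frame (~39 ms at 128 Hz) centered
moving average **for event detection only**; EDA/ESA/EDD/ESD are read from
the raw trace at the detected frames, because a moving average biases the
systolic trough upward by ~10% at typical rates — enough to corrupt ESA.

Diastoles are local maxima (scipy `find_peaks`) with prominence ≥ 0.2 ×
the within-segment range and spacing ≥ 0.1 s (caps detectable HR at
600 bpm, above anything observed); each systole is the global minimum
between consecutive diastoles of the same on-segment, which enforces the
interleaving invariant by construction.  HR pools diastole-to-diastole
intervals within on-segments — intervals never span a pause.  A recording
with fewer than two diastoles in every on-segment is flagged `no-beat`
with HR 0; its diastolic structural parameters are taken as whole-trace
means (the heart sits frozen in diastole) and systolic ones are NaN.

The orchestrator (`analyze_recording`) first estimates the dominant beat
period from the autocorrelation of the detrended trace.  Two parameters
scale with it: the activity-detection window (below) is widened to 1.2 ×
the period, and the beat refractory distance is raised to 0.6 × the
period.  The latter matters for slow rhythms (down to ~17 bpm), whose
long flat diastolic plateaus are pixel-quantized and otherwise yield
equal-height twin maxima that both survive a fixed 0.1 s spacing rule.

## Activity (on/off) detection

Coarse classification follows a sliding-SD rule: the SD of the linearly
detrended area trace in a centered window (default 1.0 s) is compared
with a noise floor (the 5th percentile of all window SDs); frames above
`k = 4` × floor are "on".  Segments shorter than 0.5 s are merged into
their neighbours.  Two additions proved necessary:

- **Homogeneous traces.**  When no window clears the threshold the trace
  is either all-on or all-off (the "floor" is then just the quietest
  beating window), and is classified by overall relative amplitude:
  detrended SD / median area above 5% means beating.  Beating swings the
  area severalfold; segmentation jitter on a frozen heart is ~1%.
- **Boundary refinement.**  The coarse window reads "on" as soon as it
  merely overlaps beating, so every bout edge is blurred by half a window
  (±0.5 s — an 8-point CAP error on a 12.4 s recording).  Each coarse
  boundary is therefore snapped to the fine-scale transition: a 5-frame
  rolling SD is thresholded at max(4 × off-floor, 0.2 × median on-SD) and
  the boundary moves to the first (onset) or last (offset) sustained
  fine-scale activity, searching only on the correct side of the coarse
  boundary.  Boundary error after refinement is a few frames, and the
  CAP of the worked-example schedule is recovered to ~0.1 point.

CAP is stored at full precision and reported rounded to integer percent.

## Synthetic phantom

The generator emulates the statistical structure the analysis assumes,
not OCM physics: a dark elliptical lumen (semi-axes a, b), a bright
elliptical wall annulus, speckled tissue.  During on-segments the
semi-axes follow a raised-cosine cycle between diastolic and systolic
values (symmetric by default; `systole_fraction` makes it asymmetric),
with phase reset to full diastole at each on-segment start so short bouts
begin cleanly.  During off-segments the geometry freezes at diastole,
matching the flat bands seen in real M-mode images of a paused heart.
Speckle is a unit-mean exponential intensity field low-pass filtered to a
~2 px correlation length and scaled to a target contrast (default 0.15),
plus additive Gaussian noise (default SD 6 on a 0–255-ish scale); it is
a stylized stand-in for coherent-imaging noise.  Identical seeds give
bitwise-identical stacks.

Defaults: 256 × 128 px frames at 2.2 µm isotropic pitch (anisotropic
pitches are supported through metadata), lumen/wall/tissue means
40/200/110.  Chamber dimensions are **not published values**: diastolic
semi-axes 55 × 45 µm with systolic = 0.6 × diastolic (FS ≈ 40%) are the
package's own plausible defaults, as are all per-stage size scales.

Stage presets pin HR and CAP to the published stage means where those are
printed — L2 277 bpm; PD1 24h 26 bpm; PD2 48h 17 bpm and CAP 5%; AD1
391 bpm and CAP 95%; CAP 100% for L3 and 61% for the PD1 worked example —
and interpolate plausible values for the remaining stages (documented in
`_STAGE_TABLE`; every non-printed entry is a synthetic default).  A
preset's schedule places the off-period first, mirroring the worked
example.  The `dCry-RNAi` genotype applies fixed multiplicative deficits
(HR × 0.80, CAP × 0.70, chamber axes × 0.85) plus per-recording jitter
(3% HR, 3-point CAP, 2% size); these effect sizes are synthetic fixtures
chosen so that group comparisons carry a detectable effect, not measured
values.

What the phantom does **not** model — and hence what passing tests do not
demonstrate about real data: depth-dependent attenuation and shadowing,
refraction, wall-intensity variation, movement of the heart within the
frame beyond pulsation, air-bubble artefacts during early pupariation,
and anatomical change of the imaging plane (A7 vs A1 segments).  Recovery
accuracies quoted below are upper bounds on real-data performance.

## Numerical choices and degenerate inputs

- Time of frame k is k / frame_rate (frame-start convention, 0-based);
  activity boundaries are snapped to frame times.
- Failed frames are dropped from traces with timestamps preserved — no
  interpolation; downstream windows operate on index positions.
- Flat traces: the noise floor is guarded by an epsilon (10⁻⁸ × intensity
  scale) so that an exactly constant trace is all-off, not 0/0.
- ESD > EDD is reported as negative FS with a warning (data-quality
  signal), not clipped.
- A t-test between two identical constant groups is defined as t = 0,
  p = 1 (scipy returns NaN there).
- CAP averaging uses the plain arithmetic mean over recordings; CDD uses
  run length × sampling interval, not midpoint interpolation — the
  simplest convention consistent with 8-h sampling, stated openly because
  finer conventions are equally defensible.

## Validation scale

Tests validate against generator ground truth and independent oracles
(brute-force BFS flood fill, per-cycle argmax, closed-form pooled t).
To keep the suite fast, unit tests use 96 × 64 px phantoms and 2–8 s
recordings; end-to-end checks use full 256 × 128 px frames at 12.4 s and
30 s; parameter-recovery runs span 17–391 bpm with durations chosen to
contain at least ~8 beats (30 s at 17 bpm down to 8 s at 391 bpm).  At
these sizes the pipeline recovers HR within 2%, EDA/ESA within 5% (in
practice ≤ 1%), and CAP within 1 point of the schedule truth.

## Known limitations

- The activity detector's percentile noise floor needs the off-state to
  occupy at least ~5–8% of the recording (or none of it); a brief pause
  in an otherwise continuously beating recording can fall below the floor
  percentile and be absorbed into the on-period.
- The autocorrelation period estimate assumes a reasonably regular
  rhythm; strongly arrhythmic beating (not modelled by the phantom, and
  no arrhythmia indices are computed) would degrade the adaptive window
  and refractory scaling.
- Diameters from axis-aligned mask extents are biased high by up to one
  pixel pitch relative to the true ellipse axes.
- CDD resolution equals the sampling interval (8 h); its convention is
  exactly recoverable on synthetic timelines but is one of several
  defensible readings of an 8-hourly design.
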