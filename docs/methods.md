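# Methods

This note documents the models, numerical choices and limitations behind
`moonwatch`, and what its synthetic-data tests do and do not establish.

## The synthetic scene (`moonwatch.scene`)

The generator renders 8-bit grayscale frames: an anti-aliased bright disk
(default 230 on a sky of 8) drifting linearly across the frame, with dark
filled 3:1 ellipses crossing the disk. Silhouettes are drawn only where
they overlap the disk — a bird against the night sky is below the exposure
floor of a moon-exposed camera. Anti-aliasing uses signed-distance
coverage clipped to [0, 1], so sub-pixel positions render consistently.

**The stated world.** Defaults model a spring full-moon validation
session: moon angular diameter 0.52°, filling ~70–74% of the frame height
(0.7–1° fields of view); drift 0.25°/min in an oblique image direction;
30 fps nominal (25 fps in test scenes, where one frame = 0.04 s, the
shortest transit observed in real footage); passerine ground speeds
truncated-normal 13 ± 3 m/s in [5, 25] (typical nocturnal passerine
groundspeeds); body lengths uniform 0.08–0.25 m (the 10–100 g passerine
assumption); assumed flight altitude 500 m; silhouette darkness uniform
10–80, i.e. contrast ≥ 150 levels against the default disk. At the default
geometry these choices reproduce the field regimes: silhouettes from ~4 px
to tens of px, transit durations from one frame to ~2.5 s.

**Flux model.** Transits are sampled from a physical flux: birds per km of
front per hour at altitude H crossing the viewing cone. The cone's
cross-section at H for moon elevation θ is an ellipse with cross-azimuth
semi-axis a = (δ/2)·H/sin θ and along-azimuth semi-axis b = a/sin θ. The
gate seen by a bird with bearing β is the ellipse's support width
perpendicular to its path, gate(β) = 2√(a²cos²ψ + b²sin²ψ) with
ψ = β − azimuth — note cos on the a-term: travel *along* the azimuth
crosses the *cross-azimuth* width. The expected transit count is
flux × E[gate] × duration; realized counts are Poisson; transiting birds'
bearings carry density p(β)·gate(β) (rejection-sampled); chord offsets are
uniform across the gate, which maps linearly to a uniform offset across
the image disk. This analytic gate is validated in the tests against an
independent Monte-Carlo rain of straight horizontal tracks over a large
square (agreement ≲0.2%).

**Ground truth.** A transit's per-frame `visible` flag is true exactly
when its rendered silhouette covers ≥ 1 px of the disk, so truth and
rendering cannot disagree; edge-skirting transits therefore exist in the
truth log with as little as one visible frame. Frame-timing jitter is
optional uniform ±20% of the nominal period. Everything is deterministic
under (config, seed): identical runs are bit-identical.

**What a green test does not establish.** The simulator has no lunar
surface texture, clouds (beyond a multiplicative fog factor), atmospheric
seeing, sensor noise, or irregular wing-beat silhouettes. Detection
scores against it bound algorithmic behaviour (linking, gating, edge
handling, timing), not real-video photometric robustness.

## Moon tracking (`moonwatch.tracking`)

Threshold → binary-mask centroid → deadband-gated correction. The binary
(not intensity-weighted) centroid makes the position estimate invariant to
exposure changes above threshold. Defaults: threshold 127; deadband 75 px
(12.5% of the 600-px working height); evaluation every 3 s; loss patience
5 evaluations.

The control law is a proportional-duration pulse per axis,
`pulse = gain·|error|·(1 + overshoot/‖e‖)`, capped at 1.5 s. The overshoot
(0.45 deadband radii, distributed along the error direction so a single
burst lands the moon inside the half-deadband hysteresis band) pushes the
moon upstream of the reference, so drift takes ~30 s at default rates to
re-trigger — the mount rests between corrections, keeping video steady.
Two details matter and were found by simulation: (i) when the *radial*
error trips the band without either axis component doing so, both
meaningfully-offset axes must be corrected together — correcting only the
larger one creates an axis-alternating limit cycle at the evaluation
cadence; (ii) the overshoot must be shared along the error direction, not
applied per axis, or the diagonal residual exceeds the hysteresis radius
and the controller chatters.

The motor interface is an abstract command sink. The simulated plant
converts pulses to pointing changes at 0.5 rpm motor rate through a 4:1
gear reduction (1.5°/s at the scope… 0.75°/s image motion at default
duty), with optional backlash. Axis sign conventions are configurable; a
one-pulse-per-axis calibration probe (`calibrate_axes`) recovers them.

## Timestamps (`moonwatch.timing`)

Capture loops in interpreted runtimes cannot hold an exact frame rate, so
per-frame times are reconstructed by piecewise-linear interpolation of
(wall time, cumulative frame count) checkpoints, written every 1 s and
flushed immediately. With ±20% period jitter the reconstruction error is
bounded by one true frame period (exact at checkpoints, monotone between
them); extrapolation past the last checkpoint is refused.

## Transit detection (`moonwatch.detect`)

Per frame: the disk is re-fit (threshold + centroid, radius = √(area/π));
a per-pixel exponential-moving-average background (τ = 1 s) is translated
to follow the fitted disk center and updated; detections are connected
components ≥ 40 levels darker than background, inside the disk + 6 px,
area ≥ 2 px. Static dark lunar features converge into the background;
movers do not. Pixels where the background's spatial gradient exceeds
20 levels/px (the disk rim, smeared by sub-pixel re-registration) are
masked with one dilation — without this, rim misregistration mimics dark
movers and floods the detector with edge artifacts.

Linking is greedy nearest-neighbour with a gating radius; once a track
has two points the gate tightens to half and centers on the
constant-velocity prediction, which keeps crossing birds separate (pure
last-position gating merges identities in crowded scenes). The gate
should be the maximum plausible per-frame displacement; the quarter-disk-
radius default under-gates fast transits below ~30 fps, so pipelines
derive it from the speed cap: `gate = 1.2·(v_max/slant)·px_per_deg/fps`.
Tracks close after 1 unmatched frame. Completeness: `single_frame` (one
detection, duration = one frame period), `edge_skirting` (every detection
within one blob-length of the rim), else `full_crossing`. Tracks with
path linearity R² < 0.8 (PCA variance ratio) are *flagged* as possible
non-birds, never deleted — there is no validated operational criterion
separating insects from birds. Flocks are single-linkage clusters of
tracks whose time intervals come within 1 s.

## Analytics (`moonwatch.analytics`)

Bearing storage is compass convention (clockwise from north); the
classical "north of east" figure is the reporting view (90° − bearing).
The projection inversion `β = A + atan2(dx, dy/sin θ)` is refused below 5°
moon altitude (foreshortening collapses the vertical image component) and
flagged wide-uncertainty above 85°. Body orientation averages per-frame
blob major-axis angles via angle doubling (axial data), disambiguates the
head end by the motion direction, and maps through the same projection;
tracks need ≥ 3 frames with elongation ≥ 1.5, otherwise orientation is
*absent*, not zero. Drift angle = bearing − orientation, wrapped to
(−180°, 180°]; the generator defines its orientation offset the same way
(body heads upwind of the realized track).

Distance-from-size uses the moon-anchored plate scale
s = δ_rad/(2·radius_px); silhouettes under 2 px yield a lower bound only.
Flight altitude is an assumption parameter (default 500 m) — moonwatching
cannot measure it per bird.

The traffic rate sums 1/gate(β) per track and divides by the watch
duration. Edge-skirting and single-frame tracks count: they are real
transits. Single-frame tracks carry no bearing, so the rate is scaled by
(n_total/n_with_bearing), which assumes they share the solved bearing
distribution. The per-mile figure uses statute miles (1.609344 km);
historical reports that imply a ×1.852 conversion appear to have used a
nautical-mile-like factor — both cannot be matched simultaneously, and
this package documents rather than reproduces that inconsistency. The
flat-earth, horizontal-flight elliptical gate is adequate below a few km
of altitude.

## Lunar ephemeris (`moonwatch.ephemeris`)

No ephemeris library is assumed. Geocentric position: truncated ELP-2000
series (32 longitude/distance terms, 30 latitude terms, planetary
additive terms, eccentricity E-factors; ~0.01° longitude accuracy),
4-term 1980 nutation, low-order ΔT. Topocentric conversion is done by
rigorous vector subtraction of the geodetic observer position in the
equatorial frame of date — the closed-form parallax-correction route was
abandoned after a transcription bug cost 0.2–0.4°; the vector route is
harder to get wrong and is validated to ≲0.15 arcmin. Validation uses
published greatest-eclipse circumstances of five total solar eclipses
(1999–2024): at those instants and ground points the topocentric moon
must coincide with the topocentric sun, which an independent,
self-contained solar oracle in the tests provides. Refraction is ignored
throughout (the ephemeris rotates direction references; it does not
point hardware).

## Video I/O (`moonwatch.videoio`)

PNG sequences round-trip losslessly and are the reference dialect. The
MJPEG-in-AVI support is a minimal RIFF container (`hdrl`/`movi`/`idx1`)
over Pillow's JPEG codec, written because no ffmpeg-backed writer exists
in the supported environment; JPEG is lossy (~2–4 mean levels on noise,
ringing at hard edges), which the detection thresholds tolerate. Neither
dialect's nominal frame rate is ever used for timing.

## Known limitations

- Detection quality is characterized on synthetic video only (see above).
- The gibbous-moon disk fit records, but does not correct, the centroid
  bias toward the lit limb; direction references inherit that bias for
  strongly gibbous phases.
- Identity swaps between birds crossing within half a gating radius of
  each other are possible; they preserve counts but can mix two tracks'
  direction solutions.
- The traffic-rate scaling for bearing-less (single-frame) tracks assumes
  exchangeability with solved tracks.
- The ephemeris ΔT model is crude outside ~1980–2050 (≲0.01° effect).
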