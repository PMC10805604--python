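# Methods

This note documents the models, estimators and numerical choices behind
`songtrack`, in the order data flows through the package.

## Geodesy (`songtrack.geo`)

All horizontal geometry assumes a spherical earth of radius
R = 6371.0088 km. At the study scale (a coastal strip of roughly
10 x 10 km) the difference from ellipsoidal geodesy is far below one
metre, and a sphere admits closed-form distance, bearing and
destination-point formulas that are trivially testable. Least-squares work
happens in a local azimuthal-equidistant frame (x east, y north, km)
centred on a configurable origin — by default the middle vector sensor —
whose round-trip error is under 1 m within 30 km. Points beyond 100 km of
a frame origin are rejected rather than silently distorted.

Bathymetry is a regular latitude/longitude raster with depth in metres,
positive down and non-positive on land; any resolution is accepted (field
products at 5 m resolution are impractical to ship, so grid resolution is
a fixture parameter throughout). Depth lookup is bilinear in the four
surrounding nodes. Distance to an isobath extracts the contour by
marching squares with linear edge interpolation (scikit-image) and takes
the minimum point-to-segment distance over the contour polylines,
evaluated in a local equirectangular frame about the query point; the
shoreline is the 0-m isobath. Both operations error loudly on
out-of-range queries and absent isobaths.

## Soundscape metrics (`songtrack.soundscape`)

Duty-cycled recorders contribute one 30-s file every 5 min (10% duty);
files are treated as unbiased samples of their hour with no gap
interpolation. Calibration maps 16-bit counts through the ADC full-scale
voltage, subtracts amplifier gain, and divides by the hydrophone
sensitivity (dB re 1 V/uPa) to micropascals. The level metric is

RMS SPL = 20 log10 sqrt( (1/T) \int_0^T p(t)^2 dt )  [dB re 1 uPa],

implemented as 10 log10 of the mean square; an all-zero file returns
-inf and is dropped downstream as missing. Hourly medians per
site/date/band suppress transients (vessels, close singers) and serial
dependence; delta-dB summaries report min, max and min - max (<= 0) per
month or breeding season. One-octave bands halve downward from the
fullband Nyquist, so a 25 kHz recording yields ... , 6.25-12.5, 3.125-6.25,
1.5625-3.125 kHz, the last being the displayed "1.56-3.12 kHz"
ambient-noise analysis band (labels truncate to two decimals in kHz; full
precision is carried internally). Band filters are 8th-order Butterworth
applied forward-backward (zero phase, flat passband). Downsampling (the
3 kHz resample giving a 0-1.5 kHz analysis band) low-passes at
0.45 x target rate with the same zero-phase filter, then resamples
polyphase; no anti-alias design was stated for the original chain, so
this is a package choice. Long-time spectral averages are Welch
periodograms per averaging block, in dB re 1 uPa^2/Hz.

## Vector-sensor directional processing (`songtrack.vector_field`)

A vector sensor records pressure p and two horizontal particle-velocity
components (vx east, vy north after applying the mounting-orientation
offset). Per STFT bin (1024-point Hann, 50% overlap at 1 kHz sampling —
chosen so a 60-s epoch holds >= 100 frames) the active intensity
Ix = Re{conj(P) Vx}, Iy = Re{conj(P) Vy} points along propagation, giving
the direction of arrival atan2(Ix, Iy), degrees clockwise from true
north, pointing from sensor to source. The normalized transport velocity

NTV = |<I>| / (c <E>),   E = |P|^2/(2 rho c^2) + rho |V|^2 / 2

equals 1 for a single plane wave (and cannot exceed 1, by AM-GM). The
published processing chain defers its exact normalization to earlier
instrument papers; the formula above is this package's own definition,
chosen to satisfy the [0, 1] bound and the role of suppressing diffuse
noise. Critically, intensity and energy are block-averaged over 8
consecutive STFT frames before forming the ratio: the instantaneous
transport ratio of even a fully diffuse field is O(1) in a single bin, and
only averaging separates directional sources (NTV -> 1) from isotropic
noise (NTV ~ M^-1/2 for M frames). Azimuthal histogram displays bin
NTV-gated azimuths (default threshold 0.75, 2-degree bins) per 60-s
epoch; a continuous singer appears as a ridge over epochs.

`trace_tracks` is an automated stand-in for analyst tracing: per-epoch
peaks above ~30% of the typical epoch maximum are linked greedily across
epochs (<= 5 degrees drift per epoch, gaps up to 5 epochs bridged for
surfacings), and competing peaks split conservatively. Externally traced
track tables are accepted as first-class input throughout; nothing
downstream depends on the tracer.

## Track matching and triangulation (`songtrack.localization`)

Azimuthal tracks from different sensors are compared with a
displacement-consistency score: bearings (circularly smoothed over 5
epochs to suppress per-epoch noise) are intersected each common epoch;
an epoch scores 1 when the intersection lies within 30 km of both
sensors and moved less than 200 m since the previous common epoch, decays
as exp(-d^2/(2 x 200 m^2)) with larger displacements d, and scores 0
without a forward intersection; the track pair's score is the median.
This score is deliberately isolated behind one function: it is a
*necessary*-condition filter (same singer in good geometry scores near
1), not a sufficient one — the ghost intersection of two *stationary*
different singers is itself stationary and can score 1, and near-endfire
pair geometry amplifies intersection jitter enough to depress even
same-singer scores.

Matching therefore rests on the physics that three bearings to one
source nearly co-intersect while mismatched bearings do not. Every
candidate triplet with at least 5 common epochs is scored by the median
per-epoch RMS angular residual of its three-bearing least-squares
triangulation (on smoothed bearings), with two guards: solutions beyond
30 km of every sensor count as misfits (three nearly parallel bearings
to different sources co-intersect far away with deceptively small
*angular* residual), and residuals are capped so one degenerate epoch
cannot dominate. Triplets above an 8-degree median residual are
discarded. The surviving cost cube is solved as an exact three-way
assignment (enumerating axis-0-to-axis-1 injections and solving the
remaining axis with the Hungarian algorithm) whenever no sensor carries
more than 7 tracks, falling back to greedy ascending-residual assignment
for larger scenes; global assignment matters because a single ambiguous
triplet chosen greedily steals tracks from two correct ones. Only
singers present on all three sensors are ever localized.

Triangulation itself minimizes the sum of squared wrapped angular
differences between observed azimuths and sensor-to-candidate bearings,
by Gauss-Newton in the local frame, seeded by the best pairwise forward
intersection (or the previous epoch's solution). Geometry with a normal
matrix condition number above 1e6 — near-parallel bearings, endfire
targets — raises a flagged failure for that epoch rather than returning
a wild solution. Per-epoch positions use bearings circularly smoothed
over 5 epochs: traced ridge azimuths are serially noisy at the
histogram-bin scale, and raw 60-s triangulations would carry several
hundred metres of jitter that downstream speed estimates would alias
into spurious travel.

Post-processing follows the published chain: (i) outlier removal — each
position's nearest-neighbour distance within its track is compared to
the track's 95% quantile, and points strictly above it are dropped in a
single pass (nearest-neighbour, not all-pairs, distances: "the closest
distance"); (ii) a centered five-step running average of coordinates,
truncated at track ends; (iii) merging of track fragments that do not
overlap in time, are separated by at most 10 min, and imply a bridging
speed of at most 6 km/h (transitively closed) — crossing azimuth tracks
are left split, merging is position-space only; (iv) automated
plausibility QC dropping epochs on land (depth <= 0 or off-grid) or
beyond 30 km of every sensor, standing in for the published manual map
inspection.

## Hourly singer metrics and states (`songtrack.movement`)

Only localizations in the first 30 min of each hour enter hourly
statistics (reducing serial dependence while spanning surfacing gaps).
Hourly mean positions are arithmetic means of latitude and longitude per
track-hour, timestamps floored to the hour. Distance to shore is taken
from the hourly mean position to the 0-m isobath; nearest-neighbour
distance is the minimum great-circle distance to other singers' mean
positions in the same hour (missing for a lone singer); d_Y, the
covariate controlling for range-dependent detectability, is the median
per-hour distance to the reference sensor. Singer-hours with mean
position beyond 6 km of the reference sensor are excluded (the radius
filter is per singer-hour; applying it per track lifetime is a
configuration switch).

Behavioural states follow the 2 km/h rule on Euclidean speeds from the
smoothed track: a step strictly above 2 km/h is travelling (a tie at
exactly 2.0 counts as stationary, with a 1e-6 km/h guard absorbing
projection round-off), an hour is travelling or stationary when at least
70% of its steps agree, otherwise "both"; hours with fewer than 5 steps
get no state (the source chain sets no floor; 5 keeps the 70% rule
meaningful). `classify_state` defaults to subsequent-fix (60-s) speeds;
the pipeline table uses a 10-fix (10-min) displacement baseline because
displacement noise is independent of the time base — with realistic
bearing noise the per-minute apparent speed of a stationary singer sits
well above 2 km/h, while a 10-min baseline pushes the noise floor below
threshold and leaves sustained travel bouts (which last tens of minutes)
at their true speed. A uniformly moving singer classifies identically at
any baseline.

Covariates for downstream regression: day-of-season (1 December = day 1,
leap-aware), hour, season-peak year (December belongs to the following
year's season), early/peak/late season segment (December/February/April),
and one-hot state binaries summing to 1 wherever a state exists. The
regression fitting itself (smoothing-spline models with AR(1) residual
structure) is out of scope; the package emits the model-ready tables.

## Shore-survey geometry (`songtrack.shore_survey`)

A theodolite fix reduces to spherical ray geometry: with eye height h and
earth radius R (optionally R/(1-k) for a refraction coefficient k,
default 0 — the original reduction software's constants are not public,
so refraction is configurable), the triangle (earth centre, eye,
sea-level target) gives central angle
gamma = asin((R+h) cos(delta) / R) - 90 deg + delta for depression delta,
and ground range R gamma. Depressions above the visible horizon dip
(acos(R/(R+h))) are rejected. Binocular reticle fixes use total
depression = horizon dip + reticles x reticle angle (a binocular-specific
configuration parameter, not printed in the source material); zero
reticles place the target exactly on the visible horizon. The two fix
kinds agree within 1 m when fed the same geometry.

Scan processing: pods beyond 10 km are excluded; timestamps round to the
hour with an era-dependent rule (first survey era floors; the second era
rounds up from minute 30, so the eras differ only for minutes in
[30, 60)); duplicate pod ids within a scan violate the no-double-count
protocol and raise; survey days with fewer than two completed scans are
excluded. Hourly medians of pod count (per day-hour counts, median across
days), shore distance and depth are produced pooled and per year,
together with first-vs-last-scan-hour differences.

## Synthetic data (`songtrack.synthetic_data`)

The generators define the package's study conditions and give every stage
a known truth.

**Geometry.** Default sensors are the three printed vector-sensor
deployments (X, Y, Z), in line and ~3 km apart, so fixture distances
match the field geometry. The coastline is modelled as the straight line
parallel to the X-Z axis passing 0.5 km inshore of Y (the deployments
sat 350-510 m off the beach); distance to shore is then an analytic
plane distance, and the linear-slope bathymetry (default 50 m/km) has its
0-m isobath exactly on that line.

**Movement.** Singers alternate stationary and travelling bouts with
exponential dwell times (defaults 40 and 15 min), drifting at 0-0.5 km/h
and travelling at 2.5-6 km/h — deliberately straddling the 2 km/h rule so
state recovery is non-trivial but identifiable. Singers repel each other
below 1.2 km, reflecting the spacing singing males maintain (field
nearest-neighbour medians run ~1-3 km); the repulsion is also what makes
cross-sensor matching well-posed, since singers closer than the bearing
noise resolution are genuinely confusable. Two scripted modes replace the
bout model when set: a diel distance-to-shore schedule (each singer
relaxes its offshore coordinate toward the hour's target at travel
speed), and an hourly travel-fraction script (a contiguous scripted
fraction of each hour is spent travelling, start offset randomized per
singer-hour) giving exactly controlled true state proportions. True
states are always derived from realized speeds with the same 2 km/h rule
the pipeline uses.

**Observations.** Bearings are true azimuths plus von Mises noise
(default concentration kappa = 200, circular SD ~4.05 deg), omitted during
periodic surfacing gaps (2 min in every 15) and beyond a 30 km
audibility radius. Vector audio renders each singer (up to three) as
repeated 2-s tonal upsweeps in disjoint 100-Hz slots of the 0.1-1 kHz
song range — disjoint so each time-frequency bin is single-source and
forms a clean azimuth ridge — as plane waves (vx = p sin(theta)/(rho c),
vy = p cos(theta)/(rho c)) plus isotropic Gaussian noise at a configurable
SNR. Soundscape rendering emits duty-cycled 30-s Gaussian band-noise
files whose per-band RMS follows an hourly dB profile, synthesized as
counts through the inverse calibration so the full chain is exercised.

**What the generators do not emulate** — and hence what passing tests do
not show about field data: realistic song phonology and spectral overlap
between singers, propagation loss and multipath, calibration drift,
vessel noise, analyst tracing variability, and non-stationary bearing
noise. Matching and state-recovery results on synthetic scenes are
statements about the estimator under the stated noise model, not about
field performance.

## What the recovery checks measure

The bundled end-to-end verification simulates six singers for 8 h with
kappa = 200 bearing noise, alternating scripted travel fractions of 0.75
and 0.25 per hour (45- and 15-min bouts, the generator's natural dwell
scale), runs the full chain, and scores three things: the fraction of
correctly matched three-sensor triplets, the RMSE of hourly mean
positions against the true means over the same epochs, and the recovered
travelling-step fraction against the scripted truth. The state metric is
evaluated over the singer-hours that survive the 6-km reference-radius
filter — the same population every hourly analysis in the package is
defined on, and the reason that filter exists: bearing noise maps to
position noise roughly linearly in range, so speed classification beyond
the study radius is dominated by jitter.

Under these conditions matching and position RMSE are stable across
seeds (100% correct triplets and RMSE well under 300 m in a 16-seed
sweep). The travelling fraction is the delicate quantity: per-step speed
estimates carry an irreducible ~1.3 km/h noise component at this bearing
noise and epoch rate, so discrimination at the 2 km/h threshold depends
on where each seed's travel-speed draws (uniform 2.5-6 km/h) fall.
Typical recovery error is below 12% relative; occasional seeds with
slow-travel draws reach ~19%. Scripted bouts shorter than the 10-min
speed baseline are partially invisible to any displacement estimator —
a resolution floor, not a bug, and the reason the verification scenario
scripts bouts at the generator's own dwell scale.

## Numerical choices and degenerate inputs

- Angular residuals wrap to (-180, 180]; all minimization is planar in
  the local frame.
- Gauss-Newton iterates at most 50 times to a 1-mm step tolerance;
  condition numbers above 1e6 raise a flagged failure.
- Quantiles use the default linear-interpolation convention; points
  exactly at the outlier quantile are kept (strict inequality drops).
- Tracks shorter than 3 points skip outlier removal; empty tracks pass
  through smoothing unchanged; hours below the epoch floor carry no
  state.
- The azimuth histogram is treated as circular (peak detection pads the
  ends); azimuths are stored in [0, 360).
- All generators are pure functions of (config, seed); library code
  contains no hidden randomness.

## Problem sizes

The bundled verification runs use scenes of 6 singers for 8 h at 60-s
epochs (~2900 singer-epochs), 100-instance triangulation oracle
comparisons on a 10-m grid, 10^4-track smoothing-variance checks, and
single-day soundscape renders at 8 kHz — sizes at which every stage's
behaviour is already asymptotic while a full run completes in minutes on
one core.
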