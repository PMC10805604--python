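# songtrack

Acoustic tracking and soundscape analysis of humpback whale singers on a
coastal breeding ground.

Passive acoustic monitoring of breeding humpback whales produces two kinds
of records: duty-cycled omnidirectional recordings, in which the aggregate
chorus of many singers shows up as band-limited ambient-noise level, and
vector-sensor (pressure + two horizontal particle-velocity channels)
recordings, from which individual singers can be tracked by the azimuth of
their song. `songtrack` implements the full processing chain that turns
both into movement-ecology tables — who sang where, how far from shore,
how far from the nearest other singer, and whether they were moving —
plus the shore-station theodolite geometry used to place visually sighted
pods on the same map. Model fitting (GAM/GAMM smoothing regressions) is
deliberately out of scope; the package emits the model-ready covariate
tables.

The core quantities:

- **RMS SPL** per 30-s file, `20 log10 sqrt((1/T) ∫ p²(t) dt)` dB re 1 µPa,
  in 1-octave bands halved down from the Nyquist (e.g. the 1.56–3.12 kHz
  ambient band of a 25 kHz recording), with hourly medians and
  ΔdB = min − max summaries describing diel chorusing cycles.
- **Azigrams**: per STFT bin the active intensity `I = Re{P* V}` points
  along propagation, giving a direction of arrival; the **normalized
  transport velocity** `NTV = |⟨I⟩| / (c⟨E⟩)` ∈ [0, 1] (1 for a plane
  wave) gates out diffuse noise, and gated azimuths histogrammed per 60-s
  epoch (**AHD**) show each singer as a ridge over time.
- **Bearing-only localization**: azimuthal tracks from three in-line
  sensors ~3 km apart are matched (displacement-consistency scores plus a
  decisive three-bearing residual test solved as a global assignment) and
  triangulated each 60 s by Gauss–Newton least squares on wrapped angular
  residuals, then cleaned by a 95%-quantile nearest-neighbour outlier
  filter, a 5-step running mean, and track merging across surfacing gaps.
- **Movement metrics**: first-30-min-of-hour subsampling, hourly mean
  positions, distance to the 0-m isobath, nearest-neighbour spacing,
  distance to the reference sensor, and stationary/travelling/both states
  from the strict 2 km/h rule with 70% hourly dominance.
- **Shore survey**: theodolite and binocular-reticle fixes reduced by
  spherical-earth ray geometry with eye-height correction, 10-km cutoff,
  era-dependent hour rounding, and hourly pod medians.

A fully ground-truthed synthetic-data module generates every input —
singer movement scenes with known states, von Mises-noised bearings with
surfacing gaps, plane-wave three-channel audio, diel soundscapes on a
30 s / 5 min duty cycle, and linear-slope bathymetry — so the whole chain
is testable end to end. See `docs/methods.md` for models, assumptions and
numerical choices.

## Worked example

Simulate six singers for 8 h monitored by the three default vector
sensors, render noisy bearings (von Mises κ = 200, ≈ 4° circular SD),
run matching, triangulation and the hourly pipeline, and score the result
against the known truth:

```python
from songtrack.pipeline import localize_scene, scene_recovery_metrics
from songtrack.synthetic_data import (
    DASAR_Y, SceneConfig, render_bearings, simulate_scene,
)

script = {h: (0.75 if h % 2 else 0.25) for h in range(24)}  # travel per hour
cfg = SceneConfig(seed=1, n_singers=6, duration_h=8.0,
                  travel_frac_by_hour=script)
truth = simulate_scene(cfg)
bearings = render_bearings(truth, cfg)
tracks = localize_scene(bearings, cfg.sensors)
m = scene_recovery_metrics(truth, tracks, DASAR_Y)
```

Output of the accompanying print statements:

```
singers simulated      : 6
tracks matched         : 6 (100% correct)
singer-hours analysed  : 36
hourly position RMSE   : 100 m
travel fraction        : true 0.499, recovered 0.441
```

All six singers were re-identified across the three sensors; hourly mean
positions land within ~100 m of truth at 3–6 km range; and the recovered
fraction of travelling steps (over the singer-hours inside the 6-km study
radius) tracks the scripted truth to about 12% relative.

The same stages are scriptable from the shell: `songtrack simulate`,
`songtrack trace`, `songtrack localize`, `songtrack hourly`,
`songtrack spl`, `songtrack survey`, `songtrack geo dist2iso` (see
`songtrack --help`).

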