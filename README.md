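# shorewatch

Habitat-use analysis for land-based cetacean scan surveys around tidal
headlands and islands.

Shore-based observers on elevated platforms scan sector-shaped viewsheds
in 10-minute snapshots, recording each sighting's compass bearing and its
reticle drop below the horizon through marine binoculars. `shorewatch`
turns such effort and sighting logs — here for harbour porpoises
(*Phocoena phocoena*) and Risso's dolphins (*Grampus griseus*) around an
island in a strong semidiurnal tidal stream — into quantitative
habitat-use results:

* **Geolocation** — reticle drop + tide-corrected observer height +
  spherical earth (refraction-corrected effective radius) → radial
  distance; bearing + distance → position in a local transverse-Mercator
  frame.
* **Detection filtering** — empirical accumulation curves (cumulative
  proportion of sightings by distance) yield per-site/species/sea-state
  *inflection radii* beyond which detection decays; only sightings inside
  those radii are analysed as a census.
* **Covariates** — seabed slope/aspect (Horn), neighbourhood SDs, current
  decomposition and spatial roughness, the Simpson–Hunter stratification
  parameter log10(h/U³), tidal state (±6.21 h around high water) and
  lunar cycle (±7.39 d around neap).
* **Core areas** — effort-balanced, overlap-weighted Gaussian kernel
  densities with an SCV-chosen 2×2 bandwidth matrix, cut into 50/60/75/95%
  percent-volume contours.
* **Habitat model** — a spatiotemporal inhomogeneous Poisson point
  process (IPP) fitted by *infinitely weighted logistic regression*
  (IWLR): sightings are response 1 / weight 1, per-scan uniform
  availability points are response 0 / weight W ≫ 1, and the penalized
  logistic slope estimates converge to the IPP log-intensity
  coefficients

  log λ(s, t) = β₀ + Σⱼ fⱼ(xⱼ(s, t)),

  with thin-plate-type smooths for ordinary covariates, cyclic cubic
  splines for tidal state, lunar cycle, aspect and current direction, a
  tensor-product smooth of (X, Y), and factor terms for site and sea
  state. Terms are chosen by forward selection scored with
  leave-one-day-out cross-validated log-likelihood (CVLL); effects are
  reported as rate ratios exp(β).
* **Synthetic studies** — a generator that produces a full study with
  known truth (bathymetry with a shallow gully, spring–neap tides,
  rectilinear currents with a wake eddy, Markov sea states, IPP
  sightings thinned by distance-dependent detection), so every stage is
  testable end to end.

## Worked example

Simulate a 20-day study, geolocate and filter the sightings, and refit
the generating IPP coefficients:

```python
import numpy as np
from shorewatch.synthetic import SyntheticScenario, simulate_dataset, default_platforms
from shorewatch.pipeline import geolocate_sightings, build_use_availability
from shorewatch.detection import DetectionLimits, apply_detection_filter
from shorewatch.ipp_model import fit_iwlr, rate_ratio
from shorewatch.smooths import SmoothTermSpec

scenario = SyntheticScenario(seed=1, days=20)
sightings, scans, env, truth = simulate_dataset(scenario)
platforms = default_platforms()

geo = geolocate_sightings(sightings, scans, platforms, env.tide)
limits = DetectionLimits({(p.id, sp, ss): r for p in platforms
                          for sp, radii in truth["inflection_radii"].items()
                          for ss, r in radii.items()})
filtered = apply_detection_filter(geo, scans, limits)

records = build_use_availability(filtered, scans, platforms, limits,
                                 env, "porpoise", seed=2)
records["depth_std"] = (records["depth"] - 25.0) / 10.0
records["cos_tidal"] = np.cos(2 * np.pi * records["tidal_state"] / 12.42)
model = fit_iwlr(records, [SmoothTermSpec(("depth_std",), "linear"),
                           SmoothTermSpec(("cos_tidal",), "linear")])
```

Printing the counts and the fitted coefficients from this run gives

```
4000 scans, 9325 sightings (9073 porpoise)
3460 sightings inside the uniform-detection region
depth effect:  +0.536  (truth +0.50), rate ratio per 10 m depth 1.71
tidal effect:  +0.633  (truth +0.60)
deviance explained: 2.1%
```

The fitted slope on standardised depth (+0.536) recovers the generating
coefficient (+0.50) within its sampling error: the sighting rate rises
by a factor of ~1.7 per 10 m of extra depth. The tidal effect is the
amplitude of a cosine in tidal state — sighting rate peaks near high
water here. Deviance explained is small, as is typical for
presence/availability models where most of the variation is Poisson
noise.

The same stages run from the shell:

```bash
shorewatch simulate --seed 1 --out run/
shorewatch geolocate --out run/
shorewatch detect    --out run/
shorewatch kde       --out run/
shorewatch fit       --out run/
shorewatch report    --out run/
```

Each stage writes its outputs (CSV / ESRI ASCII grid / GeoJSON) plus a
JSON manifest with the config snapshot, seed and input hashes; reruns
with the same manifest are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `shorewatch.geolocation` | projection, reticle→distance, platform/scan/sighting types |
| `shorewatch.detection` | accumulation curves, inflection estimation, pooling, filtering |
| `shorewatch.covariates` | terrain/current/tidal covariates, environment bundle, sampling |
| `shorewatch.kde` | effort balancing, SCV bandwidth, density surfaces, volume contours |
| `shorewatch.smooths` | spline bases and penalties for the habitat model |
| `shorewatch.ipp_model` | availability sampling, IWLR fit, CVLL, forward selection |
| `shorewatch.synthetic` | scenario generator with known truth |
| `shorewatch.pipeline` / `shorewatch.cli` | staged runner, manifests, `shorewatch` CLI |
| `shorewatch.published` | reference worked-example tables (fixtures) |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
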