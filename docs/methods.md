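# Methods

## Model

`hornwalk` implements an individual-based movement model on a static
raster landscape. Agents carry no state beyond their current and
previous cell; there is no agent–agent interaction, no energy budget,
no directional persistence and no goal — connectivity surfaces emerge
purely from local habitat responses accumulated over many independent
walks. Key assumptions: the landscape does not change during a
simulation (no seasonal or diurnal dynamics); movement through poor
habitat is impossible, so the model deliberately estimates a
"worst-case" connectivity in which agents never cross barriers; and all
agents follow identical rules (population-average behaviour, no
inter-individual variability).

### Per-step decision heuristic

At each step the 8 Moore neighbours of the current cell, minus the
previous cell, are shuffled once; candidates are then evaluated in
shuffled order and the first acceptance is taken:

1. **Hard rejections.** Roads, water (lakes and rivers share one mask —
   the rules treat them identically), crown cover strictly above the
   cover threshold, and nodata in any input layer. Nodata is
   conservatively impassable and never escape terrain, so walks cannot
   cross unmapped area.
2. **Deterministic acceptance** for passable cells whose distance to
   escape terrain is ≤ `escape_accept_dist_m`.
3. **Chance acceptance** otherwise: one uniform draw on (0, 100) per
   candidate, accepted iff strictly below
   `prob_coef_a * exp(-prob_rate_b * d)` percent. The curve exceeds
   100% near escape terrain; values ≥ 100 therefore always accept (the
   draw is still consumed, keeping the RNG stream layout uniform: one
   shuffle per step, then one draw per beyond-threshold candidate in
   list order). A chance-rejected candidate is treated as unsuitable
   for this step only; evaluation proceeds to the next candidate, and
   no candidate receives a second draw within a step.

Out-of-extent neighbours remain in the shuffled list as exit markers;
reaching one removes the agent (`left_extent`). They never pre-empt an
acceptable in-extent candidate ahead of them in the order. Exhausting
the list removes the agent as `stuck`; an agent that has made
`max_steps` moves is removed as `max_steps` before evaluating anything.
The seed cell counts as a visited cell, so a trajectory has
`n_moves + 1` cells, and `previous` is unset at the first step (all 8
neighbours are candidates).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `slope_threshold_deg` | 40 | degrees | escape terrain is slope **strictly** greater |
| `cover_threshold_pct` | 40 | % | impassable when cover **strictly** greater |
| `escape_accept_dist_m` | 400 | m | deterministic-acceptance radius |
| `prob_coef_a` | 188.21 | % | decay curve value at distance 0 |
| `prob_rate_b` | 0.0016 | 1/m | exponential decay rate |
| `max_steps` | 2000 | moves | per-agent step cap |
| `distance_metric` | euclidean | — | see below |

Strict inequalities at both thresholds mean boundary values (exactly
40° slope, exactly 40% cover) are respectively not escape terrain and
still passable. The step cap counts moves per agent; since agents are
independent this is equivalent to a global per-tick cap with all agents
started at tick 0.

### Distance to escape terrain

The distance grid is derived once at assembly. The default is the
exact centre-to-centre Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`). A `grid_ring` variant
(Chebyshev ring count × cell size) is also exposed, because with 75 m
cells no cell can sit exactly 400 m from escape terrain — the nearest
on-grid multiple beyond the radius is 450 m, so cell-multiple distances
are a defensible reading; Euclidean is the default for geometric
realism. When a landscape contains no escape terrain at all the
distance grid is +inf everywhere, which makes every cell fail the
suitability test and gives a clear diagnostic at seeding rather than a
silent all-reject walk.

## Scenario protocols

* **occurrence_dispersal** — occurrence points are mapped to cells by
  the floor convention (a point on a shared edge belongs to the
  larger-index cell); duplicate cells seed once; 100 independent agents
  run per seed cell and all accumulate into one shared usage map.
  Occurrence records are used as-is (no year filtering).
* **potential_connectivity / fire_restored / road_permeable** — 20,000
  single-agent iterations, each seeded at a uniform draw over the
  *suitable set*: passable cells within the deterministic-acceptance
  distance of escape terrain. Suitability is deliberately deterministic
  (no probabilistic clause at seeding) for reproducibility. Under fire
  rules the cover clause drops out of passability and hence out of
  suitability; under road rules road pixels stay flagged for the
  crossing analysis even though they no longer block. The road scenario
  is intended for 25 m-resolution inputs supplied natively; the
  `cell_size_m` config field is a guard against mismatched inputs, not
  a resampler.

**Reproducibility.** A master seed spawns one child RNG per trajectory
by counter (`SeedSequence(master, spawn_key=(k,))`); trajectory *k*
draws its seed cell and then its walk from that single stream, so any
trajectory reproduces in isolation and a whole run is a pure function
of (landscape, occurrences, config). The parameter-sweep utility
derives one such master seed per parameter combination and records it
in the output table, so each row can be re-run standalone.

## Aggregation and outputs

Every occupancy — the seed cell and every revisit — increments the
pixel's count, so the usage total equals the summed trajectory lengths.
The reported surface is each count divided by the most-used pixel's
count, in (0, 1], with never-used pixels as nodata (−9999 in written
rasters): "never used" is information, not a zero. Normalisation is
per map (per scenario run). Road-crossing sites are road pixels with
positive usage from the road-permeable run, ranked by count (row/col
break ties deterministically); the highlighted subset is the
nearest-rank top ⌈fraction·N⌉ with ties at the cutoff all included, so
it can exceed ⌈fraction·N⌉. Sites are reported per pixel; grouping
contiguous pixels into road sections is left to downstream GIS. The
calibration score is the fraction of occurrence points whose pixel has
positive usage; the model's acceptance bar is 0.8.

## Synthetic landscapes

The generator emulates the structural features the model responds to,
not real terrain: a gentle smoothed-noise slope field (0–25°) with
`n_ridges` dilated line segments raised above the escape threshold
(ridge tops are capped at 10% cover — rocky, not forested); crown cover
as Gaussian-smoothed noise centred on `cover_mean` and clipped to
[0, 100], whose smoothing radius sets patch size so that contiguous
dense stands genuinely block movement; and one river plus one road as
random wiggly polylines rasterized with supercover marking (a diagonal
step also marks an orthogonal cell, so barriers have no diagonal
leaks). Occurrence points are drawn uniformly from suitable cells with
a within-cell jitter. Defaults (100×100 cells at 75 m, 6 ridges at
50°, cover mean 30%) give a landscape where roughly a tenth of cells
are suitable.

What it does not emulate: realistic topography or hydrology, spatial
autocorrelation between slope and cover beyond the rocky-ridge cap,
road networks, sampling bias in occurrence data, or the geography of
any real study area. Tests passing on these landscapes demonstrate the
algorithmic contracts (rule boundaries, conservation, determinism,
calibration behaviour), not ecological validity on real GIS inputs.

## Numerical and design notes

* Random draws are continuous uniform on (0, 100) with strict `<`; a
  "number between 1 and 100" read as integers would discretise the
  acceptance curve, and the continuous reading matches "smaller than
  the probability".
* Distance-transform outputs are exact to float precision; tests
  compare against a brute-force pairwise oracle at 1e−9 m.
* Raster I/O: ESRI ASCII grids (integer grids roundtrip bit-exact) and
  single-band GeoTIFF via tifffile with the ModelPixelScale /
  ModelTiepoint / GDAL_NODATA tags; non-square pixels and missing
  georeferencing are rejected. No CRS transformation is performed —
  all layers must already share one grid.
* Desk-scale problem sizes: the test suite and acceptance script use
  100×100-cell synthetic landscapes with 2,000 iterations (and a tiny
  sealed corridor for the full 20,000-iteration bookkeeping check),
  chosen so the whole suite runs in well under a minute while still
  exercising every protocol at its defaults.

## Limitations

Slope must be supplied in degrees (no DEM-to-slope derivation);
landscapes are static; there is no dispersal through poor habitat, so
connectivity is underestimated wherever real animals make rare barrier
crossings; and the headline management conclusions of any real
application depend entirely on the quality of the input rasters and
occurrence data.
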