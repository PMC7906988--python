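# placecode

Analysis of hippocampal CA1 place coding from deconvolved calcium event
trains and position tracking — for experiments in which a head-fixed mouse
navigates a floating circular track (outer diameter 32.5 cm, width 5 cm) or
a circular open field under a two-photon microscope.

The package takes the output of an upstream imaging pipeline — a frames ×
cells matrix of non-negative calcium-transient event amplitudes
(dimensionless ΔF/F, ~30 Hz) — together with ~100 Hz position tracking, and
computes:

- **Behavior**: alignment of tracking to imaging frames, linearization of
  angular position via the track circumference, speed gating (only frames
  with speed > 20 mm/s enter spatial analyses), lap segmentation, and
  open-field coverage.
- **Rate maps**: occupancy-normalized activity-rate maps in 2-cm bins
  (circular three-bin boxcar smoothing) and 2 × 2 cm open-field bins
  (Gaussian smoothing, σ = 1.5 bins), each normalized by its maximum;
  per-lap rate maps.
- **Place-cell classification**: Skaggs spatial information

      I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄),   λ̄ = Σᵢ pᵢ λᵢ,

  in bits/event, tested against a null built from 1,000 random
  reassignments of the cell's per-frame activity across moving frames
  (chance criterion: I above the 99th percentile). Track cells must
  additionally show in-field events on ≥ 50% of laps and events in ≥ 5% of
  moving in-field frames (≥ 2% for the open field). Field location is the
  bin of maximum smoothed rate (1D) or the centroid of the normalized map
  above 0.5 (2D); field size counts bins at ≥ 50% of the maximum.
- **Stability and remapping**: recurrence, place-field correlation and
  circular field shift for all session pairs; cross-environment remapping
  statistics with the Hodges–Ajne test of circular uniformity of field
  shifts.
- **Reliability**: across-lap variance vs mean of per-bin activity rates,
  fit per cell with a total-least-squares power law y = a·xᵝ in log-log
  space; β = 1 is Poisson-like reliability, larger β means extra
  lap-to-lap variability.
- **Neural manifold**: classical MDS of the cosine dissimilarity between
  population activity vectors, manifold dimensionality (components needed
  for 90% of variance), and angular position decoding with a cross-validated
  optimal linear estimator on the (cos θ, sin θ) pair.

Because raw datasets of this kind are rarely public, the package ships a
first-class synthetic-data generator (`placecode.synth`) that emulates the
floating-track behavior (smooth laps with pauses; meandering open-field
coverage > 90% in 45 min) and cell populations (unimodal tuned cells with
per-lap reliability, untuned cells, homogeneous-Poisson controls,
log-normal event amplitudes, multi-environment remapping, multi-day
recurrence and drift), so every stage is verifiable end to end.

## Worked example

```python
import dataclasses
import placecode as pc

cfg = dataclasses.replace(
    pc.SimConfig(), duration_s=600.0, n_place_cells=5, n_untuned_cells=5,
    rng_seed=0,
)
session, truth = pc.simulate_session(cfg)
print(f"{session.n_frames} frames, {session.n_cells} cells, "
      f"{session.laps().n_complete} laps, "
      f"running fraction {session.running_fraction:.2f}")

params = pc.AnalysisParams(n_shuffles=1000)
stats, _ = pc.classify_population(session, params, seed=0)
print(stats[["cell", "spatial_info_bits_per_event", "shuffle_percentile",
             "lap_active_fraction", "is_place_cell",
             "field_location_cm", "field_size"]].round(2).to_string(index=False))

beta = pc.fit_cell_exponent(pc.per_lap_maps(session, 0)).beta
print(f"cell 0 variance-mean exponent beta = {beta:.2f}")
```

prints

```
18000 frames, 10 cells, 78 laps, running fraction 0.96
 cell  spatial_info_bits_per_event  shuffle_percentile  lap_active_fraction  is_place_cell  field_location_cm  field_size
    0                         1.59               100.0                 0.78           True               41.0       14.00
    1                         1.37               100.0                 0.71           True               73.0       14.00
    2                         1.41               100.0                 0.69           True               43.0       14.00
    3                         1.46               100.0                 0.76           True               73.0       16.00
    4                         1.47               100.0                 0.60           True               27.0       14.00
    5                         0.14                37.3                 0.97          False               23.0       80.39
    6                         0.17                57.2                 0.95          False               23.0       70.39
    7                         0.23                97.4                 0.91          False               47.0       58.39
    8                         0.14                25.2                 0.97          False               25.0       78.39
    9                         0.16                63.2                 0.95          False               47.0       64.39
cell 0 variance-mean exponent beta = 1.29
```

The five simulated tuned cells (cells 0–4) carry ~1.4 bits/event, beat all
1,000 shuffles, are active within their field on well over half of the 78
laps, and are classified as place cells with compact (~14 cm) fields at
their true locations. The five untuned cells carry almost no spatial
information, sit in the bulk of the shuffle null, and are rejected; their
"fields" are the near-degenerate plateaus of a flat map (size close to the
full 86.4 cm track). Tuned cells also show a lower variance–mean exponent
than untuned ones, mirroring the higher lap-to-lap reliability of place
cells.

A command-line interface wraps the same stages
(`placecode simulate | classify | ratemap | run-all`); see
`placecode --help`.

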