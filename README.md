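# barrierassay

Quantification pipeline for barrier-crossing sensory-integration assays in
crawling animals (e.g. *C. elegans* populations crossing a repellent copper
stripe toward a volatile attractant), starting from tracked midpoint
trajectories exported by commercial trackers.

The pipeline implements:

- **Track I/O and calibration** (`geometry_io`): tidy long-form CSV
  (canonical) and a wide per-animal-column dialect; pixel-to-mm calibration;
  animal-count estimation from the maximum number of simultaneous tracks.
- **Track exclusion filters** (`track_filter`): tracks are rejected when they
  (1) overlap user-declared exclusion regions (shadows/markings), (2) last
  less than 10 s, (3) have a bounding-box area under 30 px² (or a path length
  under the same threshold, configurable), or (4) span less than 10 px in
  both axes — with a per-track audit of the first matching criterion.
- **Barrier-crossing metrics** (`crossing_metrics`): classification of
  barrier-terminating tracks as forward / reverse / reversal (reversals —
  tracks that both start and end at the barrier — are discounted), cumulative
  net crossing fractions at 15/30/45-min checkpoints normalized by the
  estimated animal count, and the chemotactic index.
- **Spatial profiles** (`spatial_metrics`): probability of residence per
  1-mm bin of signed distance from the barrier, and mean ± SEM of the
  2-s-window Euclidean ("chord") velocity per bin, in μm/s.
- **Group statistics** (`group_stats`): per-bin unpaired Welch t-tests across
  plate replicates with step-down Holm–Šídák multiplicity correction.
- **Synthetic data with ground truth** (`synthetic_tracks`): a
  persistent-random-walk generator with distance-dependent speed laws,
  probabilistic barrier crossing with dead-zone track truncation,
  re-emergence/re-crossing, and planted degenerate tracks that exercise each
  exclusion criterion. Crossing events in the ground truth match the
  termination-based classification exactly, per seed.

## Command line

```sh
# generate a synthetic experiment (tidy CSV + ground-truth JSON sidecar)
barrierassay simulate --config config.yaml --seed 3 --out tracks.csv

# run the full pipeline on one experiment
barrierassay analyze tracks.csv --config config.yaml --out results/
# -> filter_report.csv, termination_labels.csv, crossing_summary.csv,
#    residence_profile.csv, velocity_profile.csv, profiles.png, run_log.json

# per-bin Welch + Holm-Sidak comparison between two groups of experiments
barrierassay compare --group-a a1.csv --group-a a2.csv \
                     --group-b b1.csv --group-b b2.csv \
                     --metric residence --alpha 0.05 --out cmp/
```

The YAML config may contain `arena:`, `filter:` and `simulation:` sections
plus top-level `checkpoints` and `alpha`; command-line flags override file
values. All distances are millimetres; signed distances from the barrier are
negative on the origin side and positive toward the odor; bins are half-open
`[left, right)`.

## Conventions

- Frame indices are authoritative; time is derived from the frame rate when
  absent. Default calibration: 47/1024 mm per pixel at 3 fps.
- Velocity is the Euclidean displacement across a centred 2-s window divided
  by 2 s; samples are undefined within 1 s of track ends or across frame
  gaps (gaps are never silently bridged).
- A track "terminates at the barrier" when its final point lies within the
  dead-zone half-width plus a 1-mm termination margin of the barrier midline.
  Its direction is the sign of the net odor-axis displacement over the
  trailing 2-s window.
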