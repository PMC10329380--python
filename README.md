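# smkymo — single-molecule kymograph analysis of membrane-protein dynamics

`smkymo` quantifies the dynamics of plasma-membrane (PM) proteins from
single-molecule time-lapse movies, such as VA-TIRFM acquisitions of plant
receptor-like proteins. From a multi-page TIFF stack (typical regime: up to
200 frames at a 150 ms interval, a ~30 s window matched to the residence time
of cargo in clathrin-mediated endocytosis) it computes:

- **Kymographs** — space–time images `K[t, j]` sampled along a scan line with
  an odd pixel `linewidth` (default 11), reduced across the width by max or
  mean. A stationary particle appears as a horizontal streak whose length is
  its **dwell time**, `τ = (t_end − t_start + 1)·Δt`.
- **Dwell times with censoring** — streaks touching the first or last frame
  ("overlength lines") have an unknown true duration; they are flagged
  censored and excluded from dwell summaries rather than measured.
- **Trajectory cross-validation** — a single kymograph streak can be an
  artifact of two particles successively occupying the same line position.
  Every segment is checked against 2D+t single-particle trajectories
  (LoG spot detection + nearest-neighbour linking): exactly one supporting
  trajectory with matching endpoints validates the segment; two or more
  reject it as *merged*; none rejects it as *unsupported*. This replaces
  interactive 3D-volume rotation with a deterministic, scriptable check
  (static orthogonal projections are rendered as the visual counterpart).
- **Spatial clustering index (SCI)** — mean of the top 5% pixel intensities
  divided by the mean of the bottom 5%; 1 for a homogeneous field, larger
  when fluorescence concentrates into clusters.
- **Two-channel colocalization** — sub-pixel phase-correlation registration
  of the second channel (chromatic/geometric offset), then the fraction of
  channel-A trajectories co-moving with a channel-B trajectory within a
  distance threshold (default 2 px) for a minimum number of frames (default
  3); a kymograph-pixel overlap fraction is also provided.
- **Group statistics** — two-sample *t*-tests (Welch default, Student's
  equal-variance flavor available) for dwell-time comparisons between
  treatments.

A full **synthetic VA-TIRFM simulator** (Poisson arrivals, exponential
membrane dwells, 2D diffusion, pixel-integrated Gaussian PSF, Poisson +
read-noise camera model, photobleaching, an optional misaligned second
channel with a controllable colocalized fraction) supplies ground truth, so
every stage is tested by parameter recovery rather than by eye.

## Worked example

Simulate a 200-frame, 150 ms acquisition with exponential dwells of mean
3.0 s and run the whole pipeline:

```yaml
# demo_config.yaml
seed: 2
output_dir: demo_run
simulation:
  mode: single
  params:
    n_frames: 200
    frame_interval_s: 0.15
    fov: [128, 128]
    arrival_rate: 0.5
    dwell_law: [exponential, 3.0]
scan_lines:
  mode: auto        # one line per tracked trajectory
  linewidth: 11     # must be odd
```

```sh
smkymo run --config demo_config.yaml
```

prints the stage counts:

```
outputs written to demo_run
{
  "trajectories_a": 3345,
  "scan_lines": 156,
  "segments_total": 224,
  "segments_validated": 138,
  "segments_rejected": {
    "merged": 29,
    "unsupported": 44,
    "censored": 13
  }
}
```

`demo_run/dwell.csv` then holds one row per kymograph segment:

```
stack  line_id  start_frame  end_frame  censored_l  censored_r  dwell_s     status  reason
    A       49           51         60       False       False     1.50  validated
    A       57            2         69       False       False    10.20   rejected  merged
    A       57           87        111       False       False     3.75  validated
```

The 138 validated, uncensored segments average 3.48 s — recovering the
simulated 3.0 s exponential mean (the sample of dwells long enough to
validate is biased slightly upward, and each visit is quantized to whole
exposures). The `merged` rows are fused two-particle lines that would have
inflated a naive kymograph reading; `censored` rows are overlength lines
excluded from the mean. `demo_run/sci.csv` reports SCI per channel
(here 3.16 ± 0.07 over frames), and for two-channel configs
`demo_run/coloc.csv` lists per-trajectory colocalization calls with a
bootstrap CI on the summary fraction.

The same operations are available as library calls
(`smkymo.extract_kymograph`, `smkymo.detect_segments`,
`smkymo.validate_segments`, `smkymo.compute_sci`,
`smkymo.colocalize_trajectories`, ...) and as the subcommands
`smkymo simulate|track|kymo|sci|coloc|run`.

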