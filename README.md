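# stereotrack

Multi-animal bounding-box tracking and automatic detection of
**small-displacement stereotypical behavior** — the purposeless, repetitive
movements (head shaking, tight circling) that captive animals such as
rescued slow lorises develop under chronic stress. These behaviors matter
for welfare assessment, but they are hard to monitor: they happen in
cluttered multi-animal cages, intermittently, and with almost no centroid
movement, so classical trajectory analysis sees nothing.

`stereotrack` implements the computational chain downstream of a neural
detector, for researchers and rescue-center staff who already have
per-frame animal detections (or ground-truth annotations) and want
quantitative stereotypy reports:

1. **Tracking** — ByteTrack-style two-stage association: high-confidence
   detections are matched to Kalman-predicted tracks first
   (Hungarian algorithm, cost 1 − IoU), then low-confidence detections
   rescue still-unmatched tracks, which preserves identities through
   occlusions.
2. **Movement amplitude** — each track's per-frame box aspect ratio
   r = w/h, resampled onto a uniform 1/fps grid with a natural cubic
   spline. For cage-confined animals the box shape, not the position,
   carries the movement signal.
3. **Episode detection** — binary-segmentation changepoints isolate
   fluctuating stretches; a stretch is stereotypic when its
   autocorrelation function
   ACF(k) = Σᵢ(yᵢ−ȳ)(yᵢ₋ₖ−ȳ) / Σᵢ(yᵢ−ȳ)² has a strong local maximum at a
   plausible lag; the cycle time is 1/f* with f* the dominant FFT
   frequency of the stretch.
4. **Evaluation** — detection precision/recall/AP/mAP, tracking
   MOTA = 1 − (FN+FP+IDSW)/GT and IDF1 = 2·IDTP/(2·IDTP+IDFP+IDFN), and
   cycle/duration mean absolute errors against reference annotations.

The package also provides the detector-side geometry and attention math as
deterministic array operators — notably the corner-distance box metric
MPDIoU = IoU − (d₁² + d₂²)/(w² + h²) and its loss 1 − MPDIoU — and a
seeded synthetic scene generator so the entire chain is testable without
any video data. See `docs/methods.md` for the model details and design
rationale.

## Worked example

Simulate a 30 s two-animal scene (3% detection dropout, one occlusion
window per animal), run the full pipeline, and score it:

```sh
stereotrack simulate --out demo --seed 3 --n-individuals 2 \
    --duration-s 30 --p-miss 0.03 --occlusions 1
stereotrack pipeline --det demo/det.txt --fps 25 --out-dir demo_run
cat demo_run/summary.csv
```

```
track_id,cycle_time_s,duration_s
1,3.39,7.44
2,1.59,8.92
```

Each row is one tracked individual: animal 1 shows a stereotypy bout with
a 3.39 s cycle lasting 7.44 s in total, animal 2 a faster 1.59 s cycle for
8.92 s. (An animal without stereotypy would read `None,None`.) The
generator's ground truth (`demo/episodes_gt.csv`) has periods 3.26 s and
1.60 s with durations 5.99 s and 8.45 s, so both cycles are recovered to
within ~0.13 s. Scoring makes that comparison explicit:

```sh
stereotrack evaluate-tracking --gt demo/gt.txt --pred demo_run/tracks.txt \
    --out demo_run/metrics.json
stereotrack evaluate-behavior --truth demo/episodes_gt.csv \
    --pred demo_run/summary.csv --out demo_run/mae.json
```

reports perfect tracking on this easy scene (`"MOTA": 1.0, "IDF1": 1.0,
"IDSW": 0` — dropout is bridged by the tracker's gap interpolation) and
behavior errors `"cycle_mae_s": 0.072, "duration_mae_s": 0.96` across the
two animals.

The same steps are available as library calls (`run_tracker`,
`amplitude_from_tracks`, `assemble_report`, `mota`, `behavior_mae`), which
is the recommended route for batch analyses.

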