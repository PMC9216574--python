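# cptvr — particle retracking for traction force microscopy

Traction force microscopy (TFM) measures the stresses cells exert on a
compliant gel from the motion of fiducial beads between a "cell attached"
and a "cell released" image. On soft gels a single mature focal adhesion
can displace the gel by tens of pixels within a region only a few
correlation windows wide — and there, conventional correlation trackers
(PIV and correlation-based particle tracking, cPTV) fail: the template
decorrelates and the true shift is no longer the global correlation
maximum.

`cptvr` implements **cPTV-Retracking (cPTVR)**: a strict cPTV pass plus
vector-median filtering produces a field of statistically confident
vectors, and the failed locations are then *retracked* with a correlation
search masked by the neighborhood statistics — shift magnitude within
`[0.5, 3] × |u_nei|` of the median neighboring vector and direction
within ±2 circular standard deviations — accepting local correlation
peaks that agree with the neighborhood even when they are not the global
maximum. An adaptive **enlargement factor** (EF) scales the model vector
up by 10% steps when retracking stalls, because the missing vectors are
systematically *larger* than their neighbors. The package also contains:

* a fully synthetic benchmark: designed traction fields, the Boussinesq
  half-space forward solution (analytic per-cell integrals), and rendered
  bead-image pairs (8000 beads on 512 × 512 px, E = 8 kPa, ν = 0.5);
* sub-pixel bead detection (LoG + Gaussian fitting);
* evaluation metrics (deviation ratio and per-vector accuracy
  `Acc = mean(1 − |V_g − V_m| / mean|V_g|)` over configurable regions);
* Tikhonov-regularized traction reconstruction (dense reference solver and
  Fourier-space solver, L-curve corner selection of λ).

## Worked example

```python
from cptvr import (
    BenchmarkConfig, make_benchmark, detect_beads,
    TrackConfig, track_cptv, vector_median_filter,
    retrack_field, retrack_with_enlargement,
    evaluate_truth_at, field_metrics,
)
from cptvr.detection import detections_to_array

bench = make_benchmark(BenchmarkConfig(seed=0))      # 8000 beads, 512x512
dets  = detections_to_array(detect_beads(bench.ref_image))
raw   = track_cptv(bench.ref_image, bench.def_image, dets, TrackConfig())
filt  = vector_median_filter(raw)                    # conventional cPTV
med   = retrack_field(bench.ref_image, bench.def_image, filt)   # cPTVR-median
ef    = retrack_with_enlargement(bench.ref_image, bench.def_image, med,
                                 start_field_is_median_result=True)

truth = evaluate_truth_at(bench, dets)
for name, f in [("filtered cPTV", filt), ("cPTVR-median", med), ("cPTVR-EF", ef)]:
    m = field_metrics(f, truth, bench.regions["large_force"])
    print(f"{name:14s} accuracy over large-force region: {m.accuracy:.3f}")
```

Output for seed 0:

```
filtered cPTV  accuracy over large-force region: 0.382
cPTVR-median   accuracy over large-force region: 0.900
cPTVR-EF       accuracy over large-force region: 0.933
```

The conventional tracker misses essentially every large vector (the ~52 px
displacements under the 12 kPa spot are beyond its search range and
correlation floor); retracking recovers them, and the enlargement factor
recovers the largest ones the plain median model still undershoots.

A command-line interface wraps the same pipeline:

```bash
cptvr simulate --seed 0 --out run/
cptvr track --ref run/ref.tif --def run/def.tif --out run/field.csv
cptvr retrack --ref run/ref.tif --def run/def.tif --field run/field.csv --out run/retracked.csv
cptvr evaluate --field run/retracked.csv --truth run/truth.csv --out run/metrics.json
cptvr reconstruct --field run/retracked.csv --e 8000 --nu 0.5 --out run/traction.csv
cptvr benchmark --seeds 0,1,2 --out run/compare
```

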