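# trackbias

Sampling-interval bias in GPS trajectories of flying seabirds.

GPS loggers small enough for albatrosses and petrels can fix positions
once per second, but deployments usually sample far more coarsely to save
battery. Movement metrics derived from successive fixes are
scale-sensitive in two opposing ways: at very short intervals positional
jitter (~5 m) inflates summed step lengths (*measurement error*), while
at long intervals the straight chord between fixes cuts the corners of
the real flight path and under-reports it (*interpolation error*) — the
more sinuous the flight, the more severely. `trackbias` quantifies both
effects and their knock-on consequences for behavioural-state inference.

The core computation compares each flight, sub-sampled at interval
k = 1…3600 s (path F_k, chord step distances), against the
native-resolution reference F_0 whose step distances come from the
logger's Doppler **point speed** (`d0_i = v_i Δt`, nearly free of
positional error):

* **PD_k = D_k / D_0** — proportional distance; > 1 means distance is
  overestimated, < 1 underestimated;
* **PE_dist, PE_speed, PE_angle** — per-sub-sampled-point absolute
  discrepancies between the step distance / speed / relative turning
  angle at interval k and the reference quantities inside that step's
  window.

Around this sit flight segmentation (rolling-speed rule), straightness-
index classification of flights into straight vs sinuous, a 3-state
Gaussian HMM (speed, |turning angle|) refit per interval with
kernel-utilisation-distribution overlap (VI) across intervals, and a
seeded synthetic-track generator (straight / soaring / circling /
area-restricted-search / rest regimes with realistic logger noise) that
serves as ground truth for everything.

## Worked example

A bird circling with radius r = 100 m at v = 10 m/s, sub-sampled at
k = 10 s, turns θ = vk/r = 1 radian per sub-sampled step, so each chord
measures `sin(θ/2)/(θ/2)` of the arc it replaces:

```python
from trackbias import synthetic_data as sd, resample_bias as rb
from trackbias.preprocess import as_flight

flight = as_flight(sd.gen_track(sd.circle_preset(duration=600.0))[0])
ref = rb.build_reference(flight)          # D0 from point speeds
sub = rb.subsample(flight, 10.0)          # F_10: fixes every 10 s
pe = rb.point_errors(ref, sub)

print(f"PD_10      = {rb.proportional_distance(ref, sub):.4f}")
print(f"PE_speed   = {pe['pe_speed'].mean():.3f} m/s")
print(f"PE_angle   = {pe['pe_angle'].mean():.2f} deg")
```

```
PD_10      = 0.9593
PE_speed   = 0.407 m/s
PE_angle   = 51.57 deg
```

PD_10 sits within 4×10⁻⁴ of the ideal-circle value sin(0.5)/0.5 ≈ 0.9589:
ten-second sampling already loses ~4% of a tightly circling path. The
turning-angle bias is dramatic — each 10 s step turns 57.3° while the
1 Hz reference turns 5.7° per step, a 51.6° per-point discrepancy of the
kind that destabilises state-space behavioural models.

At the other extreme, an hourly-sampled trip reported as 11,000 km
corrects to `11000 × 1.10 = 12,100 km` under the ~10% straight-flight
bias, or `11000 × 1.40 = 15,400 km` if the flight was highly sinuous
(`rb.apply_distance_bias_correction`).

The same analyses run from the shell:

```bash
trackbias bias   --seed 5 --out runs/bias            # simulated cohort
trackbias states --seed 7 --k-grid 300:1800:300 --out runs/states
trackbias simulate --preset trip --seed 3 --out runs/trip
```

`bias` prints a summary (flight counts per class, SI threshold, mean PD
for k > 60 s per class, the k at which mean PD crosses 1) and writes
per-flight PD curves, per-point PE tables and class aggregates; `states`
writes per-interval state tables, UD rasters and the VI overlap matrix.
File inputs are supported through a YAML config (`--config`) mapping
logger CSV columns onto timestamp/lat/lon/point-speed.

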