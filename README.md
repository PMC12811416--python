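# axoquant

Quantitative image analysis for axon regrowth assays in compartmentalized
(microfluidic) neuronal cultures.

When cortical axons are injured and regrow, the readouts that matter are
spread across very different image types: how far the arbor extends
(binarized axon fields), what the growth cones look like (actin-outline
masks), how much of a protein sits in the distal axon (fluorescence line
profiles), how dynamic the microtubules are (EB3 comet movies), whether two
proteins co-distribute (two-channel stacks), and where nascent-protein
puncta appear (spot fields within a tubulin mask). `axoquant` implements
each of these measurements as a tested, scriptable pipeline, together with
a synthetic-microscopy generator that renders every scene type with exact
ground truth — so each stage is verifiable end to end without access to a
microscope.

## What it computes

- **Sholl outgrowth** — intersections of a binarized axon field with
  concentric *semicircles* of increasing radius r (2 µm steps by default,
  out to 1500 µm) centered where axons exit the microgrooves, restricted to
  the half-plane of growth. An intersection is one connected run of
  foreground pixels on the discretized arc. Totals are summed in distance
  bins (0–500, 500–1000, 1000–1500 µm).
- **Growth-cone morphometry** — area *A* (µm²), perimeter *P* (µm),
  elongation ratio (major/minor axis of the second-moment best-fit
  ellipse), longest shortest path
  LSP = max<sub>u,v</sub> d<sub>geo</sub>(u, v) over skeleton nodes, and
  filopodia count (terminal skeleton branches longer than 1.0 µm, after
  pruning spurs < 0.5 µm).
- **Axial intensity profiles** — mean intensity along a 1-µm-wide segmented
  line from the axon tip 50 µm proximally; scalar background subtraction
  (no clipping); two visualization baselines (tip-anchored, or zeroing the
  distal 45–50 µm window); integrated intensity as fold change vs the
  control-group mean; terminal fraction = 100 · ∫₀¹⁰ I / ∫₀⁵⁰ I.
- **EB3 comet dynamics** — temporal difference-of-Gaussians separation
  (σ = 4 frames mobile, 50 frames static), kymograph construction along a
  1-µm-wide line, and per-dash parameters: track length = |Δx| · Δs (µm),
  lifetime = Δy/Y · T (s), growth rate = track/lifetime (µm/s), where Y is
  the kymograph height and T the acquisition time (180 s for 3 min at
  2 fps). Dashes can be traced manually or detected automatically.
- **Colocalization & puncta** — thresholded Manders coefficients
  M1 = Σ I₁[I₁>t₁ ∧ I₂>t₂] / Σ I₁[I₁>t₁] (M2 symmetric), and counts of
  detected puncta whose centroids fall inside a mask, with per-area
  densities.

## Worked example: recovering microtubule dynamics

Simulate a 3-min, 2-fps EB3 movie (50 comets with velocities uniform in
0.05–0.15 µm/s and lifetimes in 10–30 s, five static structures, Gaussian
noise at a fifth of the comet amplitude), then run the full analysis:

```python
import numpy as np
from axoquant import kymo, synthetic
from axoquant.types import Calibration, PolylineROI

cal = Calibration(pixel_size_x_um=0.1, pixel_size_y_um=0.1, frame_interval_s=0.5)
axis = PolylineROI(np.array([[10.0, 14.5], [510.0, 14.5]]), width_um=1.0)

rng = np.random.default_rng(7)
comets = synthetic.random_comets(rng, 50, axis_length_um=50.0, total_time_s=180.0)
spots = [synthetic.StaticSpot(x=rng.uniform(10, 510), y=14.5) for _ in range(5)]
movie, truth = synthetic.make_comet_movie(axis, comets, spots, shape=(30, 520),
                                          n_frames=360, calibration=cal,
                                          noise_sd=20.0, seed=7)

separated = kymo.separate_mobile_static(movie)
kg = kymo.build_kymograph(separated, axis)
params = [kymo.dash_params(d, kg) for d in kymo.detect_dashes(kg)]
summary = kymo.summarize_dynamics(params)

print(f"dashes traced: {summary['n']}")
print(f"growth rate: {summary['growth_rate_um_per_s_mean']:.4f} "
      f"+- {summary['growth_rate_um_per_s_se']:.4f} um/s "
      f"(generated mean {truth.mean_velocity:.4f})")
print(f"lifetime:    {summary['lifetime_s_mean']:.1f} "
      f"+- {summary['lifetime_s_se']:.1f} s "
      f"(generated mean {truth.mean_lifetime:.1f})")
```

Output:

```
dashes traced: 50
growth rate: 0.0964 +- 0.0040 um/s (generated mean 0.0977)
lifetime:    19.8 +- 0.8 s (generated mean 19.8)
```

All 50 simulated growth events are recovered as kymograph dashes; the
population mean growth rate agrees with the generated kinematics to ~1 %
and the mean lifetime to well under a second. The same stages are exposed
on the command line (`axoquant kymo --movie m.tif --roi line.csv ...`),
along with `axoquant <simulate|sholl|gc|profile|coloc|puncta|run>`; the
`run` subcommand drives whole simulate→analyze pipelines from one JSON
configuration and writes a manifest that makes every run byte-for-byte
repeatable.

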