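# sproutgraph

Morphometry of bead-sprouting vascular networks from time-lapse fluorescence
images: segmentation, skeleton-to-graph conversion, bifurcation-angle
statistics with an anastomosis filter, logistic growth-curve fitting,
exponential segment-length analysis — and a ground-truthed synthetic phantom
generator so the whole measurement chain can be validated without any image
downloads.

## What it does

Per bead, per day, the pipeline takes a 16-bit single-channel TIFF stack
(z-slices), max-projects it, and computes:

| stage | operations |
|---|---|
| `imaging_io` | TIFF loading, z max-projection, CSV/JSON round trips |
| `segmentation` | Gaussian blur (11 px kernel) → threshold at 1.17× mean → fill holes (boundary < 200 px) → largest component → bead detection (disk opening) → bead removal |
| `skeleton_graph` | thinning to a unit-width centerline; junction/tip/base nodes; tip/bifurcating/primary segments; iterative pruning of tip segments < 50 px (62.5 μm), primaries exempt |
| `morphometry` | A, A_c, L, λ = A/L, r_max, N_tip, N_pb, G = 1 + log2(N_tip/N_pb); tip velocity v_tip = ΔL/(Δt·N_tip) with a 2-day trailing average |
| `angles` | per degree-3 junction: arm points at 60 px arclength, smallest of the three sector angles (≤ 120°), outward-bisector bifurcation/anastomosis classification |
| `growth_stats` | logistic fits Y(t) = Y_max/(1+exp(−k(t−t1))) with t0 = t1 − 2/k and (dY/dt)_max = Y_max·k/4; semi-log exponential fits of segment-length histograms; MAPE/WMAPE; the n-sigma test; Damköhler utility |
| `phantom` | synthetic bead-sprouting networks: radial tip growth with angular jitter, Poisson branching at rate 1/l*, truncated-Normal branch angles, logistic length schedule, rendering with finite stroke width and background noise, full ground truth (per-day snapshots, JSON export) |
| `cli` | batch orchestration, per-bead fits, aggregate CSV/JSON, config files with parameter hashes |

Default calibration is 1.25 μm/pixel; all outputs are in μm / μm² / degrees /
μm per day.

## CLI

```bash
# full pipeline on a directory of TIFFs named bead<ID>_day<D>.tif
sproutgraph run --input data/ --out results/ [--config config.yaml]
          [--threshold-factor 1.17] [--prune-length 50] [--arm-length 60] ...

# same pipeline on internally generated phantom images (with ground truth)
sproutgraph phantom --out results/ --beads 2 --days 14 --seed 1 [--save-frames]

# refit growth curves from an existing records CSV
sproutgraph fit --records results/records.csv --out refit/
```

Outputs: `records.csv` (bead_id, day, condition, A_um2, Ac_um2, L_um,
lambda_um, rmax_um, N_tip, N_pb, G), `angles.csv` (per-junction angles and
classifications), `fits.json` (per-bead logistic fits, velocity series,
pooled length-distribution fits), and `config.yaml` (the exact parameters,
hashed into every output).

## Python API

```python
import sproutgraph as sg
from sproutgraph import phantom as ph

spec = ph.PhantomSpec(rng_seed=1)
net = ph.generate_network(spec)          # ground-truthed synthetic network
img = ph.render_image(net, spec, day=10)  # calibrated 16-bit-range image

seg = sg.segment_image(img)
graph = sg.prune(sg.build_graph(sg.skeletonize(seg.sprout_mask),
                                seg.bead, img.resolution_um_per_px))
record = sg.compute_record(seg, graph)    # A, L, λ, r_max, N_tip, N_pb, G
angles = sg.angle_distribution(graph)     # bifurcation angles, mean ± SEM
```
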