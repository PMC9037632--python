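# helixbend

Geometric analysis of double-stranded RNA conformational ensembles, built
for the repeat-expansion duplexes (CAG, CUG, CCUG, AUUCU repeats) whose
internal loops drive global bending, kinking and overextension — together
with a synthetic A-form conformer generator that provides ensembles with
known ground truth in place of MD trajectories.

## What it computes

For each conformation of a multi-model PDB ensemble:

* **Base-pair frames and step parameters.** Standard base reference frames
  are fitted to the ring atoms by least squares; consecutive pair frames
  are related through the mid-step-frame decomposition into the six
  rigid-body step parameters (tilt τ, roll ρ, twist Ω / shift Dx, slide Dy,
  rise Dz).
* **Groove widths.** Per-step major and minor groove widths (Mgw, mgw)
  from minimal cross-strand P–P distances on refined (smoothed,
  interpolated) phosphate polylines, plus counting of *collapsed*
  positions (Mgw < 12 Å) — the mechanical trigger for bending.
* **Bending and kinks.** A curvilinear helical axis from the per-step
  screw decomposition; the global bending angle between the end-window
  axis directions (five terminal pairs excluded); two-segment kink
  detection with position and inter-segment angle; bent-state categories
  (moderately < 40°, strongly 40–50°, extremely > 50° bent).
* **θ coordinate.** The angular change between successive vectors joining
  the centers of mass of consecutive base pairs — a per-step bending
  reaction coordinate paired with Mgw in 2D population distributions.
* **Hydrogen-bond states.** Heavy-atom donor–acceptor classification of
  non-canonical pairs (0/1/2-bond states of U·U, C·C, C·U, A·A), distorted
  closing-pair detection, and an exhaustive duplex-constrained placement
  search for the maximum simultaneous bonds per pair type.
* **Ensemble statistics.** k-means clustering on superposed heavy-atom
  coordinates, cluster average structures, binned bending tables, 2D
  (Mgw, θ / twist / slide / shift / mgw) histograms.

The generator builds ideal A-form duplexes (32° twist, 2.81 Å rise) for
arbitrary sequences and for the twelve repeat constructs — e.g.
`20xCAG` = GG(CAG)₂₀CC paired against an identical strand, giving twenty
1×1 A/A loops — and derives ensembles with imposed smooth bends, single
hinge kinks, twist/rise overextension, groove modulation and coordinate
noise, all reproducible from one seed.

## Worked example

```python
import numpy as np
from helixbend import (build_ideal_duplex, duplex_pair_frames,
                       step_parameters, groove_widths)

duplex = build_ideal_duplex("GCGAUCGAUCGCAUGCAUGCGAUC")   # 24 bp
frames, _ = duplex_pair_frames(duplex)
params = np.array([step_parameters(frames[s], frames[s + 1]).as_tuple()
                   for s in range(len(frames) - 1)])
print(params[:, 2].mean(), params[:, 5].mean(), groove_widths(duplex).mean_major())
```

prints `32.00 2.81 12.21`: the frame/step pipeline reads back the fiber
twist and rise exactly, and the calibrated groove convention puts the
ideal A-form major groove at ~12 Å.  The scripts in `examples/` walk
through each capability; `examples/bend_recovery.py` prints

```
models: 100, imposed bends 0-60 deg, noise 0.3 A
mean absolute recovery error: 2.70 deg  (criterion: <= 5)
imposed-vs-recovered rank correlation: 0.977
```

— imposed bending angles are recovered to a few degrees through the
full axis pipeline under realistic coordinate noise — and
`examples/groove_collapse.py` shows the collapse count of the 20xCAG
construct rising monotonically with the imposed bend.

## Command line

```bash
helixbend build --construct 20xCAG --out cag.pdb
helixbend perturb --construct 20xCAG --bend 60 --noise 0.3 --n 100 --seed 1 \
    --out ens.pdb --manifest truth.json
helixbend analyze ens.pdb --out-dir report --seed 1
helixbend grooves ens.pdb --threshold 12
```

`analyze` writes per-model bending/kink series, per-step parameter and
groove tables, loop H-bond states, cluster assignments, the bending table
and 2D histograms as CSV/JSON under the output directory.

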