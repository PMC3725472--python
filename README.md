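# placesim

A virtual-rat navigation simulator and hierarchical **Slow Feature Analysis
(SFA)** network for modelling hippocampal spatial codes.  The package
simulates a rodent foraging (or running a trained route) in a configurable
2-D enclosure, renders its 320° panoramic visual stream by software
raycasting, trains a three-layer SFA network with an optional ICA
sparse-coding step on that stream, and samples the trained network over the
enclosure to produce **place-field rate maps** and **head-direction tuning
curves** — entirely from visual input, with no odometry or path integration.

## The model

SFA takes a multidimensional time series **x**(t) and finds functions
g₁, …, g_k whose outputs yᵢ(t) = gᵢ(**x**(t)) vary as slowly as possible,

&nbsp;&nbsp;&nbsp;&nbsp;Δ(yᵢ) = ⟨ẏᵢ²⟩ₜ minimal,

subject to ⟨yᵢ⟩ₜ = 0 (zero mean), ⟨yᵢ²⟩ₜ = 1 (unit variance) and
⟨yᵢyⱼ⟩ₜ = 0 for i < j (decorrelation and order).  With a quadratic expansion
of the input this reduces to a generalized eigenvalue problem: whiten the
expanded signal and diagonalize the covariance of its temporal derivative;
the smallest eigenvalues are the Δ values of the slowest outputs.

A full camera frame is far too high-dimensional for a single quadratic SFA
node, so the network splits the input among small nodes with overlapping
receptive fields: a 63 × 9 node grid on the 320 × 40 pixel frame, an 8 × 2
grid on the layer-1 outputs, and a single top node integrating all sixteen
layer-2 nodes.  Every node reduces its input linearly to 16 dimensions,
expands quadratically, and applies SFA to 32 output signals.  Raw slow
signals encode position smoothly but globally; a final orthogonal **ICA
rotation** (rotation-only FastICA, tanh contrast) turns them into a sparse
code in which discrete, localized place fields appear.  Whether place or
head-direction tuning emerges is controlled purely by the movement
statistics: slow-position/fast-heading exploration yields place fields,
slow-heading movement yields head-direction tuning.

## Worked example

`examples/place_fields_demo.py` runs the whole pipeline at desk scale
(reduced architecture, 64 × 16 frames, grids 12 × 3 / 3 × 1 / 1; a few
minutes on one CPU):

```
rendering 8,000-step random walk ...
training reduced hierarchy (grids 12x3 / 3x1 / 1) + ICA ...
sampling 32 signals x (8 directions + average) ...
  signal  1: 1 region(s),  2.0% of valid area -> localized
  signal  2: 1 region(s),  4.3% of valid area -> localized
  ...
  signal 16: 1 region(s),  8.6% of valid area -> localized
16/16 leading ICA outputs are localized place fields
wrote 32 rate-map plots under place_field_plots/
```

Each line classifies one ICA output's direction-averaged rate map: a single
connected region of above-half-maximal response covering a few percent of
the box is a place field, the simulation analogue of a hippocampal place
cell's firing field.  The other examples are equally short narratives:

| script | shows |
| --- | --- |
| `examples/environments_demo.py` | enclosure presets, raycast queries, wallcheck overviews |
| `examples/trajectory_demo.py` | movement statistics: momentum vs. path straightness, waypoint routes |
| `examples/sfa_demo.py` | SFA demixing a toy nonlinear mixture; the ICA rotation |
| `examples/place_fields_demo.py` | end-to-end place-field emergence |
| `examples/head_direction_demo.py` | head-direction tuning from heading-dominated movement |

## Command-line pipeline

The same four stages are available as a shell pipeline whose flags keep the
traditional vocabulary:

```sh
placesim record star_maze 5 20 80 40 --limit 100000 --color-mode both \
    --mom 0.6 --arc 60 --path star_maze_path.txt --loop --out run/
placesim convert run/
placesim train run/frames_gray.dat --batch-size 10000 --ica --noise \
    --out run/network.npz
placesim sample run/network.npz star_maze 5 20 80 40 --signals 1 32 \
    --mode all --out run/plots
```

`record --wallcheck` writes only the two overview images (with and without
the coordinate raster) for checking a custom floor plan; `add-ica` fits the
sparse-coding layer onto an already trained network.  Custom enclosures are
plain-text files with one `x1 y1 x2 y2 [texture]` wall segment per line.

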