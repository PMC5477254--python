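# bcoms — biologically constrained optimized membrane segmentation

Segmentation of cell membranes in 3D time-lapse fluorescence recordings of
early embryos, with the parameter tuning automated away: instead of asking
the user to pick filter widths and energy weights, the pipeline runs its two
segmentation stages over an exhaustive parameter grid, scores every
candidate with an image-consistency objective, and selects the best
candidate that satisfies *biological* constraints.  It is written for
developmental biologists and image analysts who need per-cell shapes from
membrane + nuclei two-channel recordings (the motivating system is the
early *C. elegans* embryo) without hand-tuning image processing.

## Method in brief

Stage 1 segments the whole embryonic region per time point with a
region-based active contour whose curve-length (contraction) weight adapts
to image brightness, `cb(t) = c · vars(t)^b`, where `vars(t)` is the
intensity variance inside the initial region — dimmer (bleached) frames get
a weaker bias.  Candidates maximize the mean membrane intensity under the
embryo edge,

    maximize   Σ_p I_p S_p^edge / Σ_p S_p^edge
    subject to Σ_p S_p^nuc (1 − S_p^emb) = 0      (all nuclei enclosed)
               V_min / V_max ≥ 0.95                (stable embryo volume)

Stage 2 segments cells by nuclei-seeded 3D watershed of a *hybrid image*

    S_dist = EDT(~S_nuc),   I_hyb = I + α · S_dist,

box-filtered and flooded inside the stage-1 mask; `α` penalizes basins
wandering far from their own nucleus, which suppresses leakage through dim
or discontinuous membranes.  Single-voxel watershed lines plus the embryo
surface form the membrane set `S_memb`, and candidates maximize
`Σ I_p S_p^memb / Σ S_p^memb`.  Each nucleus being enclosed by its own cell
is guaranteed by the seeding.

The package also provides per-cell 3D shape features (volume, per-plane
perimeters, centroid, extents, surface area, convexity, sphericity, plus an
extended set), evaluation against a reference segmentation (percent feature
deviations, cell matching, per-voxel distance maps), adjacent-time-point
consistency, a DoG nuclei segmenter for seeds, and a synthetic embryo
generator with voxel-exact ground truth and realistic degradations
(depth attenuation, photobleaching, noise, horizontal-membrane gaps).

## Worked example

```python
import bcoms

# a degraded 7-cell recording (64x64x24 voxels, 5 time points) with truth
spec = bcoms.SyntheticEmbryoSpec(rng_seed=1)
membrane, seeds, truth = bcoms.generate_embryo(spec)

cfg = bcoms.RunConfig(seed=1)   # default grids: 6 candidates per stage
embryo, cells, logs = bcoms.run_bcoms(membrane, seeds, cfg)
print("selected:", logs["selected"])

corr = bcoms.match_cells(cells.cells, truth)
rep = bcoms.deviation_vs_truth(
    bcoms.compute_features(cells.cells, spec.spacing),
    bcoms.compute_features(truth, spec.spacing),
    corr,
)
print(f"grand mean deviation {rep.grand_mean:.2f}% +/- {rep.grand_sd:.2f}%")
```

prints

```
selected: {'stage1': {'gaussian_sigma': 1.0, 'c': 16.0, 'b': 1.0,
 'n_iter': 40, 'depth_adjust_strength': 1.0},
 'stage2': {'alpha': 1.0, 'avg_filter_size': 1}}
grand mean deviation 7.55% +/- 6.69%
```

The optimizer picked the strongest contraction bias (the contour locks onto
the bright shell; weaker biases leave it in the dark background and score
lower) and a nonzero distance weight α (at α = 0 one basin floods ~28,000
voxels of its neighbours through membrane gaps; at the selected α, 64
voxels remain mislabelled out of ~125,000 — 99.95% voxel agreement).  The
7.6% mean feature deviation is dominated by single-voxel membrane lines,
which are a noticeable fraction of the small phantom cells.

The same workflow runs from the shell:

```sh
bcoms synth --out data/                     # synthetic recording + truth
bcoms nuclei --image nuc.tif --out seeds.tif
bcoms run --membrane data/membrane.tif --seeds data/seeds.tif \
          --config cfg.yaml --out out/
bcoms features --labels out/cells.tif --spacing 0.5,1,1 --out feats.csv
bcoms eval --seg out/cells.tif --truth data/truth.tif --out dev.csv
```

`out/run_log.jsonl` holds one record per evaluated parameter set (objective,
constraint outcomes, feasibility) plus the selected sets, so every selection
is auditable.

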