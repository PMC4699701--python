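# lgncolumns

Reconstruction and order metrics for thalamo-cortical projection columns
in a standardized dLGN space.

A focal retrograde tracer injection in mouse primary visual cortex (V1)
labels a *projection column*: the population of dorsal lateral geniculate
nucleus (dLGN) relay neurons converging on that cortical point. With many
animals registered into a common nucleus space, these columns reveal the
meso-scale architecture of the geniculo-cortical projection — how cells
distribute along the column, how the column array twists and expands with
depth, and how much neighbourhood order survives from the pial surface to
the ventral border and back out to V1. This package implements that
analysis as a tested, reusable pipeline for anatomists working with
pooled point-cloud reconstructions, together with a synthetic generator
so every stage can be validated against known ground truth.

## What it computes

- **Unit columns** — each column's trajectory is a quadratic piecewise
  polynomial (5 breaks) fitted to the cell cloud, extrapolated to the
  nucleus surface mesh; cells get a unit depth t ∈ [0, 1] (0 = pial,
  1 = ventral) and a radial spread r (µm). Profiles of cell counts and
  spread per 5th percentile of depth, mean ± SEM across columns, plus a
  maximum-likelihood Rayleigh scale σ̂ = √(Σr²/2n) for the radial scatter.
- **Map stack** — per-depth 2D maps of all columns on total-least-squares
  planes at 21 iso-percentile levels, registered pairwise with a
  constrained similarity transform (expansion E ∈ [0.1, 10], rotation
  θ ∈ (−π, π]); cumulative rotation Σθ and expansion ΠE relative to the
  pial plane.
- **Order metrics** — the topographic product
  P = 1/(N(N−1)) Σ_j Σ_k log[(Π_{l≤k} Q1·Q2)^{1/2k}], normalized by the
  mean |P| of random relabellings so 0 = perfect order and ≈1 = chance,
  with Monte-Carlo permutation p-values
  (1 + #{|P_perm| ≤ |P_obs|})/(1 + n_perm); applied between neighbouring
  depth maps (topology), between the pial and ventral maps, and between
  V1 injection sites and every depth map (topography).
- **Latent scan** — pooled, shape-normalized (zero-mean/unit-variance)
  depth profiles of all metrics × groups, decomposed by autoassociative
  PLS; cumulative % explained variance and cross-validated reconstruction
  error per latent count (leave-one-out or k-fold).
- **Synthetic data** — ellipsoid nucleus with a pial cap, columns with
  prescribed rotation/expansion fields, Poisson counts, Rayleigh scatter,
  a topographic scrambling dial ρ, and low-rank profile matrices; all
  ground truth recorded.

## Worked example

```python
import numpy as np
from lgncolumns import (SyntheticConfig, make_columns, make_mesh,
                        reconstruct_column, unitize, fit_rayleigh,
                        build_map_stack, orient_stack, cumulative_trajectory,
                        end_to_end_order)
from lgncolumns.maps import align_stack

config = SyntheticConfig(seed=11)
mesh = make_mesh(config)
dataset, truth = make_columns(config, mesh)
print(f"{len(dataset.cells)} cells in {len(dataset.animal_ids)} columns")

paths, units = {}, []
for animal in dataset.animal_ids:
    cells = dataset.cells_for(animal)
    paths[animal] = reconstruct_column(cells, mesh, animal)
    units.append(unitize(cells, paths[animal]))
print(f"mean column length: {np.mean([p.total_length_um for p in paths.values()]):.0f} um")

sigma = fit_rayleigh(np.concatenate([u.r_um for u in units])).sigma_um
print(f"Rayleigh spread scale: {sigma:.1f} um (generator: {config.sigma_um})")

stack = orient_stack(build_map_stack(paths),
                     np.mean([p.ventral_point - p.pial_point
                              for p in paths.values()], axis=0))
traj = cumulative_trajectory(align_stack(stack))
print(f"cumulative rotation at ventral end: {traj.cumulative_rotation_rad[-1]:.3f} rad "
      f"(generator: {config.total_rotation_rad})")
print(f"cumulative expansion at ventral end: {traj.cumulative_expansion[-1]:.3f} "
      f"(generator: {config.total_expansion})")

result = end_to_end_order(stack, n_perm=999, seed=0)
print(f"pial vs ventral normalized P_t: {result.normalized_pt:.3f} "
      f"(p = {result.p_value:.3f})")
```

prints

```
2604 cells in 16 columns
mean column length: 783 um
Rayleigh spread scale: 24.2 um (generator: 25.0)
cumulative rotation at ventral end: 0.447 rad (generator: 0.5)
cumulative expansion at ventral end: 1.303 (generator: 1.3)
pial vs ventral normalized P_t: 0.494 (p = 0.305)
```

The pipeline recovers the generator's spread scale and rotation/expansion
fields from the raw cell clouds. The end-to-end order value (0.49, closer
to 0 than to chance at 1) shows partial preservation between the pial and
ventral maps; at the default radial scatter a single 16-column stack
often cannot certify that order at p < 0.05 — the permutation test is
honest about small-N map comparisons. `docs/methods.md` details every
model, estimator and default.

## Pipeline and CLI

Multi-group runs are driven by a YAML config (master seed, group specs —
synthetic parameters or file paths for cell/injection tables and the
boundary mesh — permutation count, PLS settings):

```
lgncolumns report -c config.yaml        # full run + JSON summary
lgncolumns simulate -c config.yaml     # just write synthetic inputs
```

Stages write CSV tables (profiles, maps, trajectories, order results,
latent scan) and a versioned `summary.json`; identical config + seed
reproduce the summary byte for byte.

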