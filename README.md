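# pknet — cellular-scale morphometry and network analysis of cardiac Purkinje fibres

The distal Purkinje network couples the ventricular conduction system to
working myocardium through a mesh of interconnected Purkinje cells.  At the
cellular scale this network can be described as a spatially embedded graph:
manually placed landmarks at furcation points and along pathways, joined by
straight centreline segments, plus closed triangle meshes for individual
segmented cells.  `pknet` implements the quantitative side of that
description for anyone studying conduction-system micro-anatomy:

- **Cell morphometry** — surface area by triangle summation, enclosed volume
  by the divergence theorem (`V = Σ v₁·(v₂×v₃)/6` over faces of a closed
  oriented surface), principal-axis length/diameters, and surface-to-volume
  ratio, for tubular and star-like Purkinje cells.
- **Network morphometry** — branch extraction (maximal furcation-free
  chains), branch-length statistics, and furcation angles split into the
  acute (α < 90°) and obtuse (β ≥ 90°) populations of the 'Y' geometry, with
  circular mean and SD (`sd = √(−2 ln R̄)`).
- **Complex-network metrics** — weighted/binary global efficiency
  `GE = ⟨1/d(i,j)⟩`, local efficiency (efficiency of each node's induced
  neighbour subgraph), characteristic path length, degree, Brandes
  betweenness normalised by `(n−1)(n−2)/2`, and Newman degree assortativity.
- **Null models and small-worldness** — degree-preserving double-edge-swap
  randomisation and band-cost latticisation, 100-network ensembles, and the
  criterion `GE_latt < GE < GE_rand` **and** `LE_rand < LE < LE_latt`.
- **Synthetic data** — generators for Purkinje-like centreline trees
  (truncated-exponential branch lengths, circular-normal furcation angles)
  and parametric cell meshes (capsules, flattened star shapes), so the whole
  pipeline is testable without imaging data.

Landmarks are read from a fiducial-style CSV (`id,x,y,z,label`, μm, RAS/LPS
frames) with a separate two-column edge list; meshes from PLY/STL/OBJ.

## Worked example

```python
import numpy as np
from pknet import (SyntheticNetworkConfig, simulate_network, extract_branches,
                   furcation_angles, complexity_report, small_world_test,
                   circular_stats)

graph = simulate_network(SyntheticNetworkConfig(seed=42, n_target_branches=500))
branches = extract_branches(graph)
angles = furcation_angles(graph)
alpha = [a.angle_deg for a in angles if a.population == "alpha"]

print(f"{len(branches)} branches, mean {branches.lengths.mean():.1f} um, "
      f"median {np.median(branches.lengths):.1f} um")
print(f"alpha angles: circular mean {circular_stats(alpha).mean:.1f} deg")
panel = complexity_report(graph, mode="weighted")
print(f"GE {panel.global_efficiency:.4f}  assortativity {panel.assortativity:.3f}")
print(small_world_test(graph, n_null=100, seed=0).verdict)
```

prints

```
499 branches, mean 87.1 um, median 68.0 um
alpha angles: circular mean 56.0 deg
GE 0.0010  assortativity -0.332
not_small_world
```

i.e. the simulated 500-branch network recovers the configured branch-length
law (mean 84.6 μm within sampling error) and acute-angle population; being a
tree, it has no redundant short paths (tiny weighted GE, zero local
efficiency), hubs attach to terminals (negative assortativity), and it fails
the small-world criterion — the expected behaviour for non-plexus Purkinje
networks.

## Analysis scripts

`analysis/` holds the numbered drivers for the full study on synthetic data;
each writes its tables under `results/`:

1. `01_simulate_dataset.py` — 16 centreline networks + 2 reference cell meshes
2. `02_cell_morphometry.py` — per-cell shape table (length, diameters, area,
   volume, S/V) for a population of tubular and star-like cells
3. `03_network_morphometry.py` — branch-length histogram, α/β angle
   populations, one-way ANOVA across stacks
4. `04_complexity_metrics.py` — per-stack metric panels and the
   assortativity bookkeeping
5. `05_small_world.py` — null ensembles (100 random + 100 lattice per stack)
   and the small-world verdict table

A `pknet` console script exposes the same steps for single inputs
(`pknet simulate network`, `pknet morphometry`, `pknet network`,
`pknet metrics`, `pknet smallworld`, `pknet pipeline run`).

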