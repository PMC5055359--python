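#!/usr/bin/env python
"""Generate the synthetic study dataset: 16 Purkinje-like centreline networks
(one per emulated confocal stack) plus the two reference cell geometries.

Networks are written in the fiducial CSV + edge-list dialect under
results/data/, meshes as PLY.  Every stack gets its own deterministic
substream of the master seed, so this script is reproducible byte for byte.
"""

from pathlib import Path

import numpy as np

from pknet.io_formats import write_edge_list, write_landmarks, write_mesh
from pknet.synthetic import (
    SyntheticCellConfig,
    SyntheticNetworkConfig,
    network_to_landmarks,
    simulate_cell_mesh,
    simulate_network,
)

MASTER_SEED = 1
N_STACKS = 16
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def stack_seed(index: int) -> int:
    return int(np.random.SeedSequence(MASTER_SEED, spawn_key=(index, 0)).generate_state(1)[0] % 2**31)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(MASTER_SEED)
    # stacks differ in extent the way imaged fields do: between a handful of
    # branches (simple non-plexus strands) and dense plexus regions
    branch_counts = np.sort(rng.integers(8, 120, size=N_STACKS))
    for i, n_branches in enumerate(branch_counts):
        stack_id = f"S{i + 1:02d}"
        cfg = SyntheticNetworkConfig(seed=stack_seed(i), n_target_branches=int(n_branches))
        graph = simulate_network(cfg)
        landmarks, edge_ids = network_to_landmarks(graph, stack_id)
        write_landmarks(landmarks, OUT / f"{stack_id}_landmarks.csv")
        write_edge_list(edge_ids, OUT / f"{stack_id}_edges.tsv")
        print(f"{stack_id}: {graph.n_nodes:4d} landmarks, {graph.n_edges:4d} edges")

    cells = [
        SyntheticCellConfig(kind="tubular", length=119.76, diameter_sagittal=13.76),
        SyntheticCellConfig(kind="star_like", length=63.27, diameter_sagittal=19.70,
                            diameter_coronal=6.79),
    ]
    for cfg in cells:
        mesh = simulate_cell_mesh(cfg)
        write_mesh(mesh, OUT / f"cell_{cfg.kind}.ply")
        print(f"cell_{cfg.kind}.ply: {mesh.n_vertices} vertices, {mesh.n_faces} faces")
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
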