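# dyncoreflow

Voxel hierarchy and directed information flow on dynamic resting-state fMRI
correlation graphs.

Resting-state fMRI is usually analysed as if the brain sat in one stationary
state for the whole scan.  It does not: the set of voxels at the top of the
functional hierarchy is replaced abruptly every few minutes.  `dyncoreflow`
quantifies that non-stationarity at the single-voxel level with two
independent instruments applied to the same sliding-window graphs:

1. **k-core percolation** on thresholded correlation graphs.  Each ~1-minute
   window of the voxel×time BOLD matrix yields a Pearson correlation matrix,
   split into an edge-disjoint *positive* channel (r > θ⁺, default 0.65) and
   an *unsigned-negative* channel (−r > θ⁻, default 0.50).  Peeling each
   binary graph (remove degree < k nodes recursively, k = 1, 2, …) assigns
   every voxel a coreness; the voxels at the maximal coreness form the
   **k_max_core**, the window's hierarchical top tier.  Coreness sums track
   the edge count E, so values are also reported *edge-scaled* (÷E).  An
   abrupt replacement of the k_max_core between windows is a **brain-state
   transition**, detected from the Jaccard overlap of consecutive top-tier
   sets.

2. **Volume entropy and afferent/efferent node capacities.**  Each window's
   channel graph becomes a metric graph (edge length ℓ = 1 − r, clipped at
   0.05) restricted to its largest connected component.  On the directed
   edge set the non-backtracking operator
   `A(h)[(u,v),(v,w)] = exp(−h·ℓ(v,w))`, w ≠ u, encodes geodesic growth on
   the universal cover; the **volume entropy** h* is the unique h ≥ 0 with
   spectral radius ρ(A(h*)) = 1 (for a d-regular graph with unit lengths,
   h* = ln(d−1) exactly).  The right Perron eigenvector of A(h*), normalised
   to sum 1, assigns each directed edge a capacity; summing a node's
   incoming (outgoing) edge capacities gives its **afferent** (**efferent**)
   capacity.  The two generally differ — information flow through a voxel
   is directional even though correlations are symmetric — and the top
   afferent voxels corroborate the k_max_core's module exchanges.

A synthetic generator plants piecewise-stationary latent states over
IC-labelled voxel modules (default-mode, visual, executive networks, …),
with tunable within-module correlation and cross-module anticorrelation, so
the whole pipeline is testable end to end without any imaging data.

## Worked example

```python
import numpy as np
from dyncoreflow import (SyntheticConfig, build_windowed_graphs,
                         detect_state_transitions, generate_voxel_timeseries)
from dyncoreflow.kcore import compute_coreness_timecourse, ic_composition
from dyncoreflow.flow import flow_timecourse

cfg = SyntheticConfig(seed=5)                 # 300 voxels x 600 frames, 3 states
ts, truth = generate_voxel_timeseries(cfg)
gs = build_windowed_graphs(ts)                # 130 windows of 84 frames, shift 4

tc = compute_coreness_timecourse(gs, "positive")
seg = detect_state_transitions(tc.kmax_sets)
print(truth.planted_transition_windows(cfg.n_frames, 84, 4))  # [40, 90]
print(seg.transitions)                                        # [40, 90]

w = 50                                        # a window inside the VN state
print(tc.edge_counts[w], tc.k_max[w], len(tc.kmax_sets[w]))   # 2211 66 67
print(dict(ic_composition(tc.kmax_sets[w], truth.ic_labels).round(3)
           .loc[lambda s: s > 0]))            # {'AN': 0.179, 'VN': 0.821}

fr = flow_timecourse(gs, "positive", window_indices=[w])[w]
print(round(fr.h, 4))                         # 22.4765
a = fr.node_capacity(ts.n_voxels, "afferent")
print(a.sum())                                # 1.0
```

The detector recovers both planted transitions exactly.  Window 50's
positive graph has 2,211 edges; its k_max_core is 67 voxels, 82% of them in
the planted visual-network module, and the top-decile afferent-capacity
voxels are drawn from the same module — the two instruments agree on which
module owns the state.  The afferent capacities sum to 1 by construction
(they partition the Perron edge capacity), and their maximum (0.024) exceeds
the efferent maximum (0.015): flow through the active module is asymmetric.

The same stages run from the shell:

```bash
dyncoreflow simulate  --out sim/ --seed 5
dyncoreflow run-all   --out run/ --seed 5        # simulate→graphs→kcore→flow→report
dyncoreflow flow      --graphs sim/timeseries.tsv --out flow/ --channel positive --stride 10
```

`run-all` writes tidy TSV/CSV tables for every stage, PNG figures, and a
`manifest.json` with config, checksums and per-stage status; re-running with
the same seed reproduces all tables bit-identically.

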