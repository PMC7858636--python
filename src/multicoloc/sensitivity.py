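"""Prior/threshold sensitivity analysis with a co-clustering heatmap.

Clustering is re-run over a grid of conditional colocalization priors and
acceptance thresholds; the co-clustering frequency of every trait pair — the
fraction of grid cells in which the pair lands in the same cluster — is
aggregated into a symmetric m x m matrix and rendered as a heatmap whose
dark blocks expose trait groupings that persist across parameter choices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import AlgorithmConfig, bb_cluster
from .priors import PriorSpec

__all__ = ["SensitivityResult", "sensitivity_grid", "export_heatmap",
           "DEFAULT_PC_GRID", "DEFAULT_THRESHOLD_GRID"]

DEFAULT_PC_GRID = (0.05, 0.02, 0.01, 0.005)
DEFAULT_THRESHOLD_GRID = ((0.5, 0.5), (0.6, 0.6), (0.7, 0.7))


@dataclass
class SensitivityResult:
    trait_names: list
    pc_grid: tuple
    threshold_grid: tuple
    cocluster_freq: np.ndarray  # m x m, symmetric, unit diagonal
    cell_partitions: dict  # (pc, (pr*, pa*)) -> list of trait-index tuples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cocluster_freq, index=self.trait_names, columns=self.trait_names
        )


def sensitivity_grid(
    region,
    base_priors: PriorSpec | None = None,
    pc_grid=DEFAULT_PC_GRID,
    threshold_grid=DEFAULT_THRESHOLD_GRID,
    corr=None,
    branch_criterion: str = "regional",
) -> SensitivityResult:
    """Run the clustering algorithm at every (pc, thresholds) grid cell and
    aggregate pairwise co-membership frequencies (cells weight equally).
    Deterministic given the inputs."""
    pc_grid = tuple(pc_grid)
    threshold_grid = tuple(tuple(t) for t in threshold_grid)
    if not pc_grid or not threshold_grid:
        raise ValueError("grids must be nonempty")
    base = base_priors or PriorSpec()
    m = region.m
    freq = np.zeros((m, m))
    partitions = {}
    n_cells = len(pc_grid) * len(threshold_grid)
    for pc, (pr_star, pa_star) in itertools.product(pc_grid, threshold_grid):
        priors = PriorSpec(scheme=base.scheme, p=base.p, pc=pc, p0_policy=base.p0_policy)
        cfg = AlgorithmConfig(
            p_r_star=pr_star, p_a_star=pa_star, branch_criterion=branch_criterion
        )
        clusters, _ = bb_cluster(region, priors, cfg, corr)
        partitions[(pc, (pr_star, pa_star))] = [c.trait_indices for c in clusters]
        for c in clusters:
            for a, b in itertools.combinations(c.trait_indices, 2):
                freq[a, b] += 1
                freq[b, a] += 1
    freq /= n_cells
    np.fill_diagonal(freq, 1.0)
    return SensitivityResult(
        trait_names=list(region.trait_names),
        pc_grid=pc_grid,
        threshold_grid=threshold_grid,
        cocluster_freq=freq,
        cell_partitions=partitions,
    )


def export_heatmap(result: SensitivityResult, path) -> tuple[Path, Path]:
    """Write the co-clustering frequency matrix as TSV and render a heatmap
    (PNG/PDF by extension) with traits ordered by hierarchical grouping of
    co-membership. Returns (image path, TSV path)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    result.to_frame().to_csv(tsv_path, sep="\t", float_format="%.10g")

    m = result.cocluster_freq.shape[0]
    if m > 2:
        dist = 1.0 - result.cocluster_freq
        np.fill_diagonal(dist, 0.0)
        order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    else:
        order = np.arange(m)
    mat = result.cocluster_freq[np.ix_(order, order)]
    names = [result.trait_names[i] for i in order]

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * m), max(3.5, 0.5 * m)))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="Greys")
    ax.set_xticks(range(m), names, rotation=90, fontsize=8)
    ax.set_yticks(range(m), names, fontsize=8)
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    ax.set_title("Cluster stability across priors and thresholds", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, tsv_path
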