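"""Self-organizing-map clustering with Pearson-centered distance.

Probes and samples are clustered on rectangular SOM grids (defaults 6x6 /
100,000 iterations for probes and 3x3 / 20,000 for samples, initial
learning rate 0.02). Items are mean-centered per vector before training;
the best-matching node is chosen under the Pearson-centered distance
d = 1 - r, while node updates use ordinary vector-space averaging. For
display, items are ordered node-by-node with complete-linkage hierarchical
ordering inside each node, and written as a CDT file readable by
Cluster/TreeView-style heatmap viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .core_io import ExpressionMatrix

PROBE_DEFAULTS = {"grid": (6, 6), "iterations": 100_000}
SAMPLE_DEFAULTS = {"grid": (3, 3), "iterations": 20_000}


def pearson_centered_distance(x, y) -> float:
    """1 - Pearson correlation; 0 for identical shape, 2 for anti-correlated."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def _center_rows(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=1, keepdims=True)


def _pearson_distances_to_nodes(item: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Vector of 1-r distances from one centered item to every node."""
    nc = nodes - nodes.mean(axis=1, keepdims=True)
    item_norm = np.linalg.norm(item)
    node_norms = np.linalg.norm(nc, axis=1)
    denom = item_norm * node_norms
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nc @ item / np.where(denom > 0, denom, np.inf)
    return 1.0 - np.where(np.isfinite(r), r, 0.0)


@dataclass
class SOMGrid:
    shape: tuple[int, int]
    node_vectors: np.ndarray  # (rows*cols, n_features)
    assignment: dict[str, int]  # item label -> node index (row-major)
    iterations: int
    initial_learning_rate: float
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    def items_of_node(self, node: int) -> list[str]:
        return [label for label, n in self.assignment.items() if n == node]


def _assign(items: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    centered = _center_rows(items)
    return np.array(
        [int(np.argmin(_pearson_distances_to_nodes(it, nodes))) for it in centered]
    )


def quantization_error(items: np.ndarray, nodes: np.ndarray) -> float:
    """Mean Pearson-centered distance of items to their nearest node."""
    centered = _center_rows(items)
    return float(
        np.mean([np.min(_pearson_distances_to_nodes(it, nodes)) for it in centered])
    )


def train_som(
    matrix: ExpressionMatrix,
    axis: str = "probes",
    grid: tuple[int, int] | None = None,
    iterations: int | None = None,
    lr0: float = 0.02,
    seed: int = 0,
) -> SOMGrid:
    """Train a sequential SOM on probes or samples of an expression matrix.

    At step t of T, one item (cyclic over a seeded shuffle) pulls its
    best-matching node and every node within a hard neighborhood radius
    toward itself with learning rate ``lr0 * (1 - t/T)``. The radius
    shrinks linearly from the grid diagonal to 0. Nodes are initialized
    as a seeded sample of distinct items; final assignment is by
    Pearson-centered distance.
    """
    if axis not in ("probes", "samples"):
        raise ValueError("axis must be 'probes' or 'samples'")
    defaults = PROBE_DEFAULTS if axis == "probes" else SAMPLE_DEFAULTS
    grid = grid or defaults["grid"]
    iterations = iterations if iterations is not None else defaults["iterations"]
    data = matrix.values if axis == "probes" else matrix.values.T
    labels = matrix.probe_ids if axis == "probes" else matrix.sample_ids
    n_items, _ = data.shape
    rows, cols = grid
    n_nodes = rows * cols
    if n_nodes > n_items:
        raise ValueError(f"grid {grid} has more nodes than items ({n_items})")

    items = _center_rows(data.astype(float))
    rng = np.random.default_rng(seed)
    nodes = items[rng.choice(n_items, size=n_nodes, replace=False)].copy()
    order = rng.permutation(n_items)

    node_rc = np.array([(i // cols, i % cols) for i in range(n_nodes)], dtype=float)
    grid_dist = np.linalg.norm(node_rc[:, None, :] - node_rc[None, :, :], axis=-1)
    max_radius = float(grid_dist.max())

    for t in range(iterations):
        item = items[order[t % n_items]]
        lr = lr0 * (1.0 - t / iterations)
        radius = max_radius * (1.0 - t / iterations)
        bmu = int(np.argmin(_pearson_distances_to_nodes(item, nodes)))
        neighbors = grid_dist[bmu] <= radius
        nodes[neighbors] += lr * (item - nodes[neighbors])

    assignment = {labels[i]: int(n) for i, n in enumerate(_assign(data, nodes))}
    return SOMGrid(
        shape=grid,
        node_vectors=nodes,
        assignment=assignment,
        iterations=iterations,
        initial_learning_rate=lr0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ordering and CDT export
# ---------------------------------------------------------------------------


def _pearson_condensed(data: np.ndarray) -> np.ndarray:
    centered = _center_rows(data)
    sd = centered.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = centered / safe[:, None]
    r = (z @ z.T) / z.shape[1]
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def _linkage_order(data: np.ndarray, method: str) -> list[int]:
    if data.shape[0] <= 2:
        return list(range(data.shape[0]))
    link = sch.linkage(_pearson_condensed(data), method=method)
    return list(sch.leaves_list(link))


def som_ordering(som: SOMGrid, data: np.ndarray, labels: list[str],
                 linkage: str = "complete") -> list[str]:
    """Order items by node index, then complete-linkage order within nodes."""
    index = {label: i for i, label in enumerate(labels)}
    ordered: list[str] = []
    for node in range(som.n_nodes):
        members = [l for l in labels if som.assignment[l] == node]
        if not members:
            continue
        sub = data[[index[l] for l in members]]
        ordered.extend(members[i] for i in _linkage_order(sub, linkage))
    return ordered


def order_and_export(
    som_probes: SOMGrid,
    som_samples: SOMGrid,
    matrix: ExpressionMatrix,
    linkage: str = "complete",
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Reorder the matrix by both SOMs and optionally write a CDT file."""
    row_order = som_ordering(som_probes, matrix.values, matrix.probe_ids, linkage)
    col_order = som_ordering(som_samples, matrix.values.T, matrix.sample_ids, linkage)
    ordered = matrix.data.loc[row_order, col_order]
    if path is not None:
        write_cdt(ordered, path)
    return ordered


def write_cdt(ordered: pd.DataFrame, path: str | Path) -> None:
    """Write the Cluster/TreeView tab-delimited CDT dialect."""
    lines = ["\t".join(["GID", "NAME", "GWEIGHT"] + list(ordered.columns))]
    lines.append("\t".join(["EWEIGHT", "", ""] + ["1"] * ordered.shape[1]))
    for i, (probe, row) in enumerate(ordered.iterrows()):
        cells = [f"GENE{i}X", str(probe), "1"] + [repr(float(v)) for v in row]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cdt(path: str | Path) -> pd.DataFrame:
    """Read back a CDT written by :func:`write_cdt` (values only)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    samples = header[3:]
    rows, index = [], []
    for line in lines[2:]:
        cells = line.split("\t")
        index.append(cells[1])
        rows.append([float(v) for v in cells[3:]])
    return pd.DataFrame(rows, index=index, columns=samples)
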