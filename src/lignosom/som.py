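"""Hexagonal self-organizing map over gene expression profiles.

The map groups genes with similar expression profiles into nodes laid out
on a hexagonal grid, so that neighbouring nodes hold similar profiles and
no arbitrary cluster-count threshold is needed. Sizing follows the standard
rule: units = X * sqrt(N) with X = 1.5 by default, decomposed into a
near-square grid (rows = ceil(sqrt(u)), cols = round(u / rows)); for the
2,227-gene curated set this yields a 9 x 8 = 72-node map with ~31 genes per
node on average.

Training is classic online SOM: the total number of single-profile
presentations is 100x the unit count, genes are presented in reshuffled
cycles, the learning rate declines linearly (0.05 -> 0.01), and the
neighbourhood is a hard ("bubble") disc on the hexagonal grid whose radius
declines linearly from the 2/3 quantile of all unit-to-unit distances to
zero. Codebook vectors are initialized from a random sample of data rows.
Everything is driven by a single seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SOMConfig:
    x: float = 1.5                     # map-scaling factor in units = x*sqrt(N)
    target_genes_per_node: int = 35    # informational calibration, not enforced
    epochs_multiplier: int = 100       # presentations = multiplier * units
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_quantile: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("x must be > 0")
        if self.epochs_multiplier <= 0:
            raise ValueError("epochs_multiplier must be > 0")
        if not self.alpha_start > self.alpha_end > 0:
            raise ValueError("need alpha_start > alpha_end > 0")


@dataclass
class SOMModel:
    rows: int
    cols: int
    coords: np.ndarray        # units x 2 hexagonal layout coordinates
    codebook: np.ndarray      # units x features
    assignment: pd.Series     # gene -> unit (0-based, row-major)
    quant_error: float
    feature_names: list
    config: SOMConfig

    @property
    def units(self) -> int:
        return self.rows * self.cols

    def unit_position(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.cols)


def map_size(n: int, x: float = 1.5) -> tuple[int, int, int]:
    """Number of map units and grid shape for ``n`` profiles.

    u = x * sqrt(n); rows = ceil(sqrt(u)); cols = round(u / rows) (half away
    from zero, at least 1). Returns (units, rows, cols).
    """
    if n < 1:
        raise ValueError("need at least one profile")
    u = x * math.sqrt(n)
    rows = math.ceil(math.sqrt(u))
    cols = max(1, math.floor(u / rows + 0.5))
    return rows * cols, rows, cols


def hex_coords(rows: int, cols: int) -> np.ndarray:
    """Offset hexagonal layout: odd rows shifted by half a unit, row pitch
    sqrt(3)/2, so each interior unit has exactly six unit-distance
    neighbours."""
    coords = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            coords[r * cols + c] = (c + 0.5 * (r % 2),
                                    r * math.sqrt(3.0) / 2.0)
    return coords


def train_som(data: pd.DataFrame, config: SOMConfig = SOMConfig(),
              rows: int | None = None, cols: int | None = None) -> SOMModel:
    """Train a hexagonal SOM on gene profiles (rows = genes, columns =
    individual replicate samples).

    Deterministic given ``config.seed``. The final assignment maps every
    gene to its best-matching unit (nearest codebook vector, Euclidean).
    """
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError("empty expression matrix")
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression values")
    if rows is None or cols is None:
        _, rows, cols = map_size(len(data), config.x)
    units = rows * cols
    if len(data) < units:
        import warnings
        warnings.warn(f"fewer profiles ({len(data)}) than map units "
                      f"({units}); map will be sparse", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    n = len(values)
    init_idx = rng.choice(n, size=units, replace=n < units)
    codebook = values[init_idx].astype(float).copy()

    coords = hex_coords(rows, cols)
    diff = coords[:, None, :] - coords[None, :, :]
    grid_dist = np.sqrt((diff ** 2).sum(axis=2))
    radius0 = float(np.quantile(grid_dist, config.radius_quantile))

    steps = config.epochs_multiplier * units
    order = rng.permutation(n)
    pos = 0
    for t in range(steps):
        if pos == n:
            order = rng.permutation(n)
            pos = 0
        xvec = values[order[pos]]
        pos += 1
        frac = t / max(steps - 1, 1)
        alpha = config.alpha_start + frac * (config.alpha_end
                                             - config.alpha_start)
        radius = radius0 * (1.0 - t / steps)
        d2 = ((codebook - xvec) ** 2).sum(axis=1)
        bmu = int(d2.argmin())
        nbr = grid_dist[bmu] <= radius
        nbr[bmu] = True
        codebook[nbr] += alpha * (xvec - codebook[nbr])

    d2 = ((values[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    assignment = pd.Series(d2.argmin(axis=1), index=data.index, name="node")
    quant_error = float(np.sqrt(d2.min(axis=1)).mean())
    return SOMModel(rows=rows, cols=cols, coords=coords, codebook=codebook,
                    assignment=assignment, quant_error=quant_error,
                    feature_names=list(data.columns), config=config)


@dataclass
class NodeStats:
    """Node x substrate summary of a trained map."""

    means: pd.DataFrame        # node x substrate mean log2 expression
    fold_change: pd.DataFrame  # node x substrate linear FC vs control
    counts: pd.Series          # genes per node
    control: str


def node_stats(som: SOMModel, expr: pd.DataFrame,
               condition_of_column: pd.Series | dict,
               control: str = "maltose") -> NodeStats:
    """Per-node, per-substrate mean expression with replicates combined.

    ``condition_of_column`` maps each expression column to its substrate.
    The node fold change vs control is the linear ratio implied by the
    difference of node mean log2 values (the log2 values already carry the
    pseudocount, so 2^(mean_s - mean_control) is the pseudocounted ratio of
    mean normalized counts). Empty nodes get missing means and are never
    selected downstream.
    """
    cond = pd.Series(condition_of_column)
    missing = [c for c in expr.columns if c not in cond.index]
    if missing:
        raise ValueError(f"no substrate label for columns: {missing}")
    if not som.assignment.index.equals(expr.index):
        expr = expr.loc[som.assignment.index]
    units = som.units
    substrates = list(pd.unique(cond.loc[expr.columns]))
    means = pd.DataFrame(np.nan, index=range(units), columns=substrates)
    counts = pd.Series(0, index=range(units), name="n_genes")
    grouped = expr.groupby(som.assignment)
    for node, block in grouped:
        counts[node] = len(block)
        for sub in substrates:
            cols = [c for c in expr.columns if cond[c] == sub]
            means.loc[node, sub] = block[cols].to_numpy().mean()
    if control not in substrates:
        raise ValueError(f"control substrate {control!r} not among columns")
    fc = pd.DataFrame(
        np.exp2(means.to_numpy() - means[[control]].to_numpy()),
        index=means.index, columns=means.columns)
    means.index.name = fc.index.name = counts.index.name = "node"
    return NodeStats(means=means, fold_change=fc, counts=counts,
                     control=control)
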