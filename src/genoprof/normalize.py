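"""Groupwise, gene-free normalization of tile depths across libraries.

One scale factor per library is found by iterative trimming of the pooled
(both-strand) tile list:

1. preliminary factors from raw aligned-read sizes (inverse totals);
2. drop the globally least-expressed half of the tiles (these are expected to
   be the generally non-expressed strand);
3. drop tiles with very low depth in any single library;
4. iterate: trim a fraction from each end of the expression ranking, keep the
   least cross-library-variable fraction of the survivors (by NRMSD), recompute
   each library's effective size as the unnormalized depth sum over the kept
   tiles, and refresh the factors — until the factors stop changing.

Factors are reported rescaled to geometric mean 1; only ratios matter.
No variance weighting of libraries is applied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .tiling import STRAND_INDEX, TileDepthMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    low_strand_fraction: float = 0.50
    min_depth_floor: float = 10.0
    expr_trim: float = 0.10
    variability_keep: float = 0.20
    convergence_tol: float = 1e-6
    max_iter: int = 100

    def validate(self) -> None:
        for name in ("low_strand_fraction", "expr_trim", "variability_keep"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.expr_trim * 2 >= 1:
            raise ValueError("expr_trim too large: 2*expr_trim must be < 1")
        if self.min_depth_floor < 0:
            raise ValueError("min_depth_floor must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NormalizationResult:
    libraries: list[str]
    factors: np.ndarray  # geometric mean 1
    retained_tiles: np.ndarray  # flat (strand * n_tiles + tile) indices
    iterations: int
    trace: list[np.ndarray] = field(default_factory=list)
    converged: bool = True

    def factor_of(self, label: str) -> float:
        return float(self.factors[self.libraries.index(label)])

    def report(self, config: NormalizationConfig) -> dict:
        return {
            "libraries": self.libraries,
            "factors": [float(f) for f in self.factors],
            "retained_tiles": int(self.retained_tiles.size),
            "iterations": self.iterations,
            "converged": self.converged,
            "config": {
                "low_strand_fraction": config.low_strand_fraction,
                "min_depth_floor": config.min_depth_floor,
                "expr_trim": config.expr_trim,
                "variability_keep": config.variability_keep,
                "convergence_tol": config.convergence_tol,
                "max_iter": config.max_iter,
            },
        }


def _geomean_one(inverse_sizes: np.ndarray) -> np.ndarray:
    """Rescale positive values to geometric mean 1."""
    logs = np.log(inverse_sizes)
    return np.exp(logs - logs.mean())


def preliminary_factors(matrix: TileDepthMatrix) -> np.ndarray:
    """Factors proportional to 1 / raw aligned size, geometric mean 1."""
    sizes = matrix.raw_sizes()
    for lab, s in zip(matrix.libraries, sizes):
        if s <= 0:
            raise ValueError(f"library {lab!r} has zero total depth")
    return _geomean_one(1.0 / sizes)


def nrmsd(values: np.ndarray, factors: np.ndarray) -> float:
    """Normalized RMS deviation from the geometric mean of one tile's depths.

    With x_i = value_i * factor_i and g = geomean(x), returns
    sqrt(mean((x - g)^2)) / g.  All normalized values must be positive.
    """
    x = np.asarray(values, dtype=float) * np.asarray(factors, dtype=float)
    if np.any(x <= 0):
        raise ValueError("nrmsd requires positive normalized values")
    g = math.exp(float(np.mean(np.log(x))))
    return float(np.sqrt(np.mean((x - g) ** 2)) / g)


def _nrmsd_rows(values: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Vectorized :func:`nrmsd` over rows (tiles x libraries)."""
    x = values * factors[np.newaxis, :]
    g = np.exp(np.mean(np.log(x), axis=1))
    return np.sqrt(np.mean((x - g[:, np.newaxis]) ** 2, axis=1)) / g


def normalize(
    matrix: TileDepthMatrix, config: NormalizationConfig | None = None
) -> NormalizationResult:
    """Run the full iterative groupwise normalization. See module docstring."""
    config = config or NormalizationConfig()
    config.validate()
    if matrix.n_libraries < 2:
        raise ValueError("normalization needs at least 2 libraries")

    n_tiles = matrix.axis.n_tiles
    # pooled tile list over both strands, flat index = strand*n_tiles + tile
    values = matrix.depths.reshape(matrix.n_libraries, 2 * n_tiles).T  # tiles x libs
    coords = np.arange(2 * n_tiles)

    factors = preliminary_factors(matrix)
    trace: list[np.ndarray] = [factors.copy()]

    # stage 2: remove globally least-expressed fraction (pooled both strands),
    # ranked by preliminary-factor-normalized mean
    norm_mean = (values * factors[np.newaxis, :]).mean(axis=1)
    order = np.lexsort((coords, norm_mean))
    n_drop = int(math.floor(config.low_strand_fraction * len(coords)))
    keep = np.sort(order[n_drop:])
    if keep.size == 0:
        raise ValueError("low-expression removal emptied the tile set")

    # stage 3: per-library depth floor on unnormalized depths
    ok = np.all(values[keep] >= config.min_depth_floor, axis=1)
    keep = keep[ok]
    if keep.size == 0:
        raise ValueError("min-depth floor emptied the tile set")

    converged = False
    iterations = 0
    retained = keep
    for iterations in range(1, config.max_iter + 1):
        vals = values[keep]
        norm_mean = (vals * factors[np.newaxis, :]).mean(axis=1)
        order = np.lexsort((coords[keep], norm_mean))
        k = int(math.floor(config.expr_trim * keep.size))
        mid = order[k : keep.size - k] if keep.size - 2 * k > 0 else np.array([], int)
        if mid.size == 0:
            raise ValueError("expression trim emptied the tile set")
        mid_idx = keep[np.sort(mid)]

        dev = _nrmsd_rows(values[mid_idx], factors)
        n_keep = max(1, int(round(config.variability_keep * mid_idx.size)))
        order = np.lexsort((coords[mid_idx], dev))
        retained = np.sort(mid_idx[order[:n_keep]])

        effective = values[retained].sum(axis=0)
        if np.any(effective <= 0):
            raise ValueError("zero effective library size over retained tiles")
        new_factors = _geomean_one(1.0 / effective)
        change = float(np.max(np.abs(new_factors / factors - 1.0)))
        factors = new_factors
        trace.append(factors.copy())
        if change < config.convergence_tol:
            converged = True
            break

    if not converged:
        log.warning("normalization did not converge in %d iterations", config.max_iter)

    return NormalizationResult(
        libraries=list(matrix.libraries),
        factors=factors,
        retained_tiles=retained,
        iterations=iterations,
        trace=trace,
        converged=converged,
    )


def merge_replicates(
    matrix: TileDepthMatrix,
    factors: np.ndarray,
    groups: dict[str, str],
) -> TileDepthMatrix:
    """Average factor-normalized depths across replicate groups.

    ``groups`` maps library label -> group tag; output libraries are the group
    tags in order of first appearance, each the mean of ``depth * factor`` over
    its members.
    """
    factors = np.asarray(factors, dtype=float)
    missing = [lab for lab in matrix.libraries if lab not in groups]
    if missing:
        raise ValueError(f"libraries missing a group tag: {missing}")
    out_labels: list[str] = []
    for lab in matrix.libraries:
        g = groups[lab]
        if g not in out_labels:
            out_labels.append(g)
    out = np.zeros((len(out_labels), 2, matrix.axis.n_tiles))
    for gi, g in enumerate(out_labels):
        members = [i for i, lab in enumerate(matrix.libraries) if groups[lab] == g]
        scaled = matrix.depths[members] * factors[members, np.newaxis, np.newaxis]
        out[gi] = scaled.mean(axis=0)
    return TileDepthMatrix(matrix.axis, out_labels, out)


def write_factors_tsv(result: NormalizationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("library\tfactor\n")
        for lab, f in zip(result.libraries, result.factors):
            fh.write(f"{lab}\t{f:.10g}\n")


def write_run_report(result: NormalizationResult, config: NormalizationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.report(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
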