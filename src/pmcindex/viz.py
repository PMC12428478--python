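"""Surface (3x3 sheet) and radar renderings of PMC scores.

The nine scored dimension values of one policy are arranged row-major into
a 3x3 grid ([X1 X2 X3; X4 X5 X6; X7 X8 X9]); the surface diagram is an
interpolated 3-D sheet over that grid whose concave regions mark weak
dimensions. The radar chart shows the corpus-wide mean of each dimension
on nine axes scaled [0, 1]. Interpolation is bilinear at a fixed 30x30
resolution by default — cosmetic only, the grid values are exact.

Rendering is deterministic: an Agg backend, a fixed SVG hash salt and no
embedded timestamps, so the same input yields byte-identical SVG output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import ColumnMeans, PMCResult
from .errors import PMCError
from .rounding import round_half_up
from .schema import VariableSchema

plt.rcParams["svg.hashsalt"] = "pmcindex"

_GRID_IDS = (("X1", "X2", "X3"), ("X4", "X5", "X6"), ("X7", "X8", "X9"))


@dataclass(frozen=True)
class SurfaceMatrix:
    """Row-major 3x3 arrangement of one policy's nine dimension scores."""

    code: str
    grid: tuple[tuple[float, float, float], ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.grid, dtype=float)


def surface_matrix(result: PMCResult) -> SurfaceMatrix:
    """Pure reshaping of the nine scored dimension values; no smoothing."""
    scores = result.primary_scores.scores
    rows = []
    for row_ids in _GRID_IDS:
        row = []
        for pid in row_ids:
            if pid not in scores:
                raise PMCError(f"policy {result.code!r} missing score for {pid!r}")
            row.append(float(scores[pid]))
        rows.append(tuple(row))
    return SurfaceMatrix(code=result.code, grid=tuple(rows))


def _bilinear(grid: np.ndarray, resolution: int) -> np.ndarray:
    """Bilinear upsample of a 3x3 grid to resolution x resolution."""
    xs = np.linspace(0.0, 2.0, resolution)
    i = np.clip(np.floor(xs).astype(int), 0, 1)
    t = xs - i
    # interpolate rows then columns
    rows = grid[i, :] * (1 - t)[:, None] + grid[i + 1, :] * t[:, None]
    out = rows[:, i] * (1 - t)[None, :] + rows[:, i + 1] * t[None, :]
    return out


def _savefig(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    if not path.exists() or path.stat().st_size == 0:
        raise OSError(f"failed to write {path}")
    return path


def render_surface(
    matrix: SurfaceMatrix, path: str | Path, resolution: int = 30
) -> Path:
    """Render one policy's interpolated 3-D surface to PNG/SVG."""
    z = _bilinear(matrix.as_array(), resolution)
    xs = np.linspace(1, 3, resolution)
    xg, yg = np.meshgrid(xs, xs)
    fig = plt.figure(figsize=(4, 3.2))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(xg, yg, z, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_zlim(0, 1)
    ax.set_title(matrix.code)
    ax.set_xticks([1, 2, 3])
    ax.set_yticks([1, 2, 3])
    return _savefig(fig, path)


def render_surfaces(
    results: Sequence[PMCResult], outdir: str | Path, fmt: str = "png"
) -> list[Path]:
    """Batch mode: one surface file per policy, in the given result order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [
        render_surface(surface_matrix(r), outdir / f"{i:02d}_{r.code}.{fmt}")
        for i, r in enumerate(results, start=1)
    ]


def render_contact_sheet(
    results: Sequence[PMCResult], path: str | Path, ncols: int = 7
) -> Path:
    """Composite sheet of all surfaces, laid out left-to-right, top-to-bottom."""
    n = len(results)
    nrows = -(-n // ncols)
    fig = plt.figure(figsize=(2.2 * ncols, 2.0 * nrows))
    xs = np.linspace(1, 3, 30)
    xg, yg = np.meshgrid(xs, xs)
    for i, r in enumerate(results, start=1):
        ax = fig.add_subplot(nrows, ncols, i, projection="3d")
        z = _bilinear(surface_matrix(r).as_array(), 30)
        ax.plot_surface(xg, yg, z, cmap="viridis", vmin=0.0, vmax=1.0)
        ax.set_zlim(0, 1)
        ax.set_title(r.code, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    return _savefig(fig, path)


def render_radar(
    means: ColumnMeans, path: str | Path, schema: VariableSchema | None = None
) -> Path:
    """Radar chart of per-dimension mean scores, nine axes scaled [0, 1].

    Axis values are the ColumnMeans entries exactly (no renormalization).
    """
    ids = list(schema.scored_ids) if schema is not None else list(means.primary_means)
    values = [float(means.primary_means[pid]) for pid in ids]
    angles = np.linspace(0, 2 * np.pi, len(ids), endpoint=False)
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    closed_angles = np.concatenate([angles, angles[:1]])
    closed_values = values + values[:1]
    ax.plot(closed_angles, closed_values, "o-", linewidth=1.5)
    ax.fill(closed_angles, closed_values, alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(
        [f"{pid}\n{round_half_up(means.primary_means[pid]):.2f}" for pid in ids],
        fontsize=8,
    )
    ax.set_ylim(0, 1)
    return _savefig(fig, path)
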