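"""Cell-based virtual construction site.

The site is a 92 x 84 grid of 1 m^2 cells.  Four 30 x 30 building blocks
(3600 cells) are separated by two orthogonal road corridors.  Building cells
carry an integer workload in 1..20, a static hazard drawn from
Triangular(0, mode, 200) and possibly a situational-constraint flag; three
tower cranes sweep 15-degree danger sectors of radius 20 whose cells carry a
dynamic hazard drawn uniformly from [160, 200].  The effective hazard of a
cell is the maximum of its static and crane hazards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rand import DrawBuffer
from .config import ConfigurationError, SiteConfig

__all__ = ["SiteGrid", "generate_site", "update_crane_zones", "consume_and_replenish"]

# Building block corners (x0, y0); each block is BLOCK x BLOCK cells.
BLOCK = 30
_BLOCK_ORIGINS = ((10, 10), (52, 10), (10, 44), (52, 44))
# Road corridors: a vertical corridor in x and a horizontal corridor in y.
_ROAD_X = (44, 48)
_ROAD_Y = (40, 44)

_NEIGHBOR_OFFSETS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


@dataclass
class CraneState:
    pivot: tuple[float, float]
    jib_length: float
    heading_idx: int  # which angular sector (of 360/step) the jib occupies
    sectors: list[np.ndarray]  # flat cell indices per heading


class SiteGrid:
    """Mutable site state backed by flat numpy arrays (row-major, y*W + x)."""

    def __init__(self, config: SiteConfig, rng: np.random.Generator):
        self.config = config
        w, h = config.grid_width, config.grid_height
        n = w * h
        self.width, self.height = w, h

        self.is_building = np.zeros(n, dtype=bool)
        self.is_road = np.zeros(n, dtype=bool)
        xs = np.arange(n) % w
        ys = np.arange(n) // w
        for x0, y0 in _BLOCK_ORIGINS:
            self.is_building |= (xs >= x0) & (xs < x0 + BLOCK) & (ys >= y0) & (ys < y0 + BLOCK)
        self.is_road |= (xs >= _ROAD_X[0]) & (xs < _ROAD_X[1])
        self.is_road |= (ys >= _ROAD_Y[0]) & (ys < _ROAD_Y[1])
        self.is_road &= ~self.is_building
        if int(self.is_building.sum()) != config.n_building_cells:
            raise ConfigurationError("building layout does not produce the required cell count")

        self.workload = np.zeros(n, dtype=np.int64)
        self.base_hazard = np.zeros(n, dtype=np.float64)
        self.crane_hazard = np.zeros(n, dtype=np.float64)
        self.effective_hazard = np.zeros(n, dtype=np.float64)
        self.has_constraint = np.zeros(n, dtype=bool)

        bidx = np.flatnonzero(self.is_building)
        self.building_idx = bidx
        self.workload[bidx] = rng.integers(1, config.workload_max + 1, size=bidx.size)
        self.base_hazard[bidx] = rng.triangular(0.0, config.hazard_mode, 200.0, size=bidx.size)
        self.has_constraint[bidx] = rng.random(bidx.size) < (
            config.constraint_coeff * self.workload[bidx] / config.workload_max
        )
        self.effective_hazard = self.base_hazard.copy()

        # cranes: pivots at the centroids of the first n_cranes blocks
        n_steps = int(round(360.0 / config.crane_step_deg))
        self.cranes: list[CraneState] = []
        for x0, y0 in _BLOCK_ORIGINS[: config.n_cranes]:
            pivot = (x0 + BLOCK / 2.0, y0 + BLOCK / 2.0)
            sectors = self._precompute_sectors(pivot, config.jib_length, n_steps)
            heading = int(rng.integers(0, n_steps))
            self.cranes.append(CraneState(pivot, config.jib_length, heading, sectors))
        self._apply_crane_sectors(rng)

        # 8-neighbourhoods, precomputed for the movement model
        self.neighbors_building = self._precompute_neighbors(building_only=True)
        self.neighbors_walkable = self._precompute_neighbors(building_only=False)

        # buffered scalar draws for the replenishment hot path
        self._ubuf = DrawBuffer()
        self._tri_buf: np.ndarray | None = None
        self._tri_i = self._ubuf.chunk

    # -- construction helpers -------------------------------------------------

    def _precompute_sectors(
        self, pivot: tuple[float, float], radius: float, n_steps: int
    ) -> list[np.ndarray]:
        """Flat cell indices under the jib for each discrete heading.

        A cell belongs to the sector whose half-open angular interval
        contains its centre, provided the centre lies within the jib radius;
        the union over all headings is therefore exactly the jib disk.
        """
        px, py = pivot
        step = 2.0 * math.pi / n_steps
        x_lo = max(0, int(px - radius) - 1)
        x_hi = min(self.width - 1, int(px + radius) + 1)
        y_lo = max(0, int(py - radius) - 1)
        y_hi = min(self.height - 1, int(py + radius) + 1)
        sectors: list[list[int]] = [[] for _ in range(n_steps)]
        for y in range(y_lo, y_hi + 1):
            for x in range(x_lo, x_hi + 1):
                dx, dy = x + 0.5 - px, y + 0.5 - py
                if dx * dx + dy * dy > radius * radius:
                    continue
                theta = math.atan2(dy, dx) % (2.0 * math.pi)
                sectors[int(theta / step) % n_steps].append(y * self.width + x)
        return [np.asarray(s, dtype=np.int64) for s in sectors]

    def _precompute_neighbors(self, building_only: bool) -> list[np.ndarray]:
        """8-neighbour flat indices for every cell (building or walkable)."""
        ok = self.is_building if building_only else (self.is_building | self.is_road)
        out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * (self.width * self.height)
        for idx in np.flatnonzero(self.is_building | self.is_road):
            x, y = int(idx % self.width), int(idx // self.width)
            nbs = []
            for dx, dy in _NEIGHBOR_OFFSETS:
                nx, ny = x + dx, y + dy
                if 0 <= nx < self.width and 0 <= ny < self.height:
                    nidx = ny * self.width + nx
                    if ok[nidx]:
                        nbs.append(nidx)
            out[idx] = np.asarray(nbs, dtype=np.int64)
        return out

    # -- crane dynamics -------------------------------------------------------

    def _apply_crane_sectors(self, rng: np.random.Generator) -> None:
        """Redraw the danger-zone hazard for every crane's current sector."""
        cfg = self.config
        touched = [c.sectors[c.heading_idx] for c in self.cranes]
        for crane, cells in zip(self.cranes, touched):
            draws = rng.uniform(cfg.crane_hazard_low, cfg.crane_hazard_high, size=cells.size)
            np.maximum.at(self.crane_hazard, cells, draws)
        for cells in touched:
            self.effective_hazard[cells] = np.maximum(
                self.base_hazard[cells], self.crane_hazard[cells]
            )

    def rotate_cranes(self, rng: np.random.Generator) -> None:
        """Advance every jib one angular step and refresh the danger zones."""
        old = [c.sectors[c.heading_idx] for c in self.cranes]
        for crane in self.cranes:
            crane.heading_idx = (crane.heading_idx + 1) % len(crane.sectors)
        for cells in old:
            self.crane_hazard[cells] = 0.0
            self.effective_hazard[cells] = self.base_hazard[cells]
        self._apply_crane_sectors(rng)

    # -- workload -------------------------------------------------------------

    def _next_triangular(self, rng: np.random.Generator) -> float:
        i = self._tri_i
        if i >= self._ubuf.chunk:
            self._tri_buf = rng.triangular(
                0.0, self.config.hazard_mode, 200.0, size=self._ubuf.chunk
            )
            i = 0
        self._tri_i = i + 1
        return float(self._tri_buf[i])

    def consume(self, cell: int, amount: float, rng: np.random.Generator) -> None:
        """Remove ``amount`` workload from ``cell``; replenish on depletion."""
        if amount > self.workload[cell]:
            raise ValueError("cannot consume more workload than the cell holds")
        self.workload[cell] -= int(amount)
        if self.workload[cell] == 0 and self.config.replenish and self.is_building[cell]:
            cfg = self.config
            wl = 1 + self._ubuf.integer(rng, cfg.workload_max)
            self.workload[cell] = wl
            bh = self._next_triangular(rng)
            self.base_hazard[cell] = bh
            ch = self.crane_hazard[cell]
            self.effective_hazard[cell] = bh if bh > ch else ch
            self.has_constraint[cell] = (
                self._ubuf.uniform(rng) < cfg.constraint_coeff * wl / cfg.workload_max
            )

    # -- export ---------------------------------------------------------------

    def snapshot_layers(self) -> dict[str, np.ndarray]:
        """2-D views of the main layers (row-major, shape height x width)."""
        shape = (self.height, self.width)
        return {
            "workload": self.workload.reshape(shape),
            "base_hazard": self.base_hazard.reshape(shape),
            "effective_hazard": self.effective_hazard.reshape(shape),
        }

    def write_layers(self, prefix: str) -> list[str]:
        """Write each layer as a delimited text grid with a header line."""
        paths = []
        for name, layer in self.snapshot_layers().items():
            path = f"{prefix}_{name}.txt"
            with open(path, "w") as fh:
                fh.write(f"# width={self.width} height={self.height}\n")
                np.savetxt(fh, layer, fmt="%.3f" if layer.dtype.kind == "f" else "%d")
            paths.append(path)
        return paths


def generate_site(config: SiteConfig, rng: np.random.Generator) -> SiteGrid:
    """Build the virtual site: layout, workloads, hazards and cranes."""
    return SiteGrid(config, rng)


def update_crane_zones(grid: SiteGrid, rng: np.random.Generator) -> SiteGrid:
    """Advance the crane jibs one step (functional wrapper around the method)."""
    grid.rotate_cranes(rng)
    return grid


def consume_and_replenish(
    grid: SiteGrid, cell: int, amount: float, rng: np.random.Generator
) -> SiteGrid:
    """Consume workload at ``cell``; depleted building cells are redrawn."""
    grid.consume(cell, amount, rng)
    return grid
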