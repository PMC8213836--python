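"""Sensor-surface model: hexagonal tessellation and stochastic lever placement.

The simulated biosensor surface is a square tiled with flat-topped hexagons of
in-radius ``r`` (default 2.5 nm).  Each hexagon may hold at most one DNA
nanolever at its center, so the hexagon centers — a triangular lattice with
spacing ``2r`` — enforce a hard minimum lever-to-lever distance of ``2r``
(5 nm at the default), the physical packing limit set by DNA radius and
electrostatic repulsion.

A target *mean* inter-lever distance ``d`` is realized stochastically: each
hexagon is occupied independently with probability equal to the area ratio of
the tiling hexagon to a hexagon of in-radius ``d/2``, which reduces to
``(2r/d)**2``.  On average one lever then falls per hexagon of in-radius
``d/2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seeding import spawn_rng

__all__ = [
    "HexGrid",
    "LeverField",
    "build_hex_grid",
    "occupancy_probability",
    "place_levers",
    "save_lever_field",
    "load_lever_field",
]

DEFAULT_IN_RADIUS_NM = 2.5


@dataclass(frozen=True)
class HexGrid:
    """Centers of a hexagonal tessellation of a square surface.

    Attributes
    ----------
    side_length_nm:
        Side of the square surface in nm.
    in_radius_nm:
        In-radius of each hexagon; adjacent centers are ``2 * in_radius_nm``
        apart.
    centers:
        ``(N, 2)`` array of center coordinates in nm, row-major by lattice row.
    """

    side_length_nm: float
    in_radius_nm: float
    centers: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.side_length_nm <= 0 or self.in_radius_nm <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_centers(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class LeverField:
    """Anchor points of DNA nanolevers placed on a :class:`HexGrid`.

    ``occupancy_p`` is the per-hexagon Bernoulli probability that realized the
    target ``mean_distance_nm``; regeneration with the same grid and seed
    reproduces the anchors exactly.
    """

    anchors: np.ndarray = field(repr=False)
    mean_distance_nm: float
    occupancy_p: float
    seed: int
    side_length_nm: float
    in_radius_nm: float

    @property
    def n_levers(self) -> int:
        return len(self.anchors)


def build_hex_grid(
    side_length_nm: float, in_radius_nm: float = DEFAULT_IN_RADIUS_NM
) -> HexGrid:
    """Tile a square of side ``side_length_nm`` with hexagons of given in-radius.

    Centers form a triangular lattice with spacing ``2 * in_radius_nm``: rows
    run along x with row pitch ``in_radius_nm * sqrt(3)`` and odd rows offset
    by ``in_radius_nm``.  Only centers strictly inside the square are kept
    (partial boundary hexagons are dropped).

    Raises
    ------
    ValueError
        If dimensions are non-positive or the square is smaller than
        ``4 * in_radius_nm`` (too small to host a meaningful tiling).
    """
    if in_radius_nm <= 0 or side_length_nm <= 0:
        raise ValueError("side_length_nm and in_radius_nm must be positive")
    if side_length_nm < 4 * in_radius_nm:
        raise ValueError(
            f"side_length_nm={side_length_nm} must be >= 4*in_radius_nm="
            f"{4 * in_radius_nm}"
        )
    r = float(in_radius_nm)
    side = float(side_length_nm)
    dy = r * np.sqrt(3.0)
    ys = np.arange(r, side, dy)
    rows = []
    for j, y in enumerate(ys):
        x0 = r if j % 2 == 0 else 2 * r
        xs = np.arange(x0, side, 2 * r)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    centers = np.concatenate(rows) if rows else np.empty((0, 2))
    return HexGrid(side_length_nm=side, in_radius_nm=r, centers=centers)


def occupancy_probability(
    mean_distance_nm: float, in_radius_nm: float = DEFAULT_IN_RADIUS_NM
) -> float:
    """Per-hexagon occupation probability realizing a mean lever distance.

    The probability is the ratio of the tiling-hexagon area to the area of a
    hexagon with in-radius ``mean_distance_nm / 2``; hexagon area is
    ``2*sqrt(3)*r**2``, so the shape factors cancel and the ratio is
    ``(in_radius_nm / (mean_distance_nm/2))**2``, clamped to 1.
    """
    if mean_distance_nm <= 0:
        raise ValueError("mean_distance_nm must be positive")
    if in_radius_nm <= 0:
        raise ValueError("in_radius_nm must be positive")
    return min(1.0, (2.0 * in_radius_nm / mean_distance_nm) ** 2)


def place_levers(grid: HexGrid, mean_distance_nm: float, seed: int) -> LeverField:
    """Occupy grid centers with levers by independent Bernoulli draws.

    Each hexagon receives a lever with probability
    :func:`occupancy_probability`, so the expected lever count is
    ``grid.n_centers * p`` and the realized mean inter-lever distance matches
    ``mean_distance_nm`` in the area-ratio sense.

    Raises
    ------
    ValueError
        If ``mean_distance_nm < 2 * grid.in_radius_nm`` — a mean distance
        below the lattice spacing cannot be realized.
    """
    if mean_distance_nm < 2 * grid.in_radius_nm:
        raise ValueError(
            "mean_distance_nm must be >= 2*in_radius_nm "
            f"({2 * grid.in_radius_nm} nm); got {mean_distance_nm}"
        )
    p = occupancy_probability(mean_distance_nm, grid.in_radius_nm)
    rng = spawn_rng(seed, "place_levers")
    mask = rng.random(grid.n_centers) < p
    return LeverField(
        anchors=grid.centers[mask].copy(),
        mean_distance_nm=float(mean_distance_nm),
        occupancy_p=p,
        seed=int(seed),
        side_length_nm=grid.side_length_nm,
        in_radius_nm=grid.in_radius_nm,
    )


def save_lever_field(fld: LeverField, csv_path: str | Path) -> Path:
    """Write anchors as ``lever_id,x_nm,y_nm`` CSV plus a JSON sidecar.

    The sidecar (same stem, ``.json`` suffix) carries the generating
    parameters so the field can be reproduced or reloaded losslessly.
    """
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "lever_id": np.arange(fld.n_levers),
            "x_nm": fld.anchors[:, 0],
            "y_nm": fld.anchors[:, 1],
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "side_length_nm": fld.side_length_nm,
        "in_radius_nm": fld.in_radius_nm,
        "mean_distance_nm": fld.mean_distance_nm,
        "occupancy_p": fld.occupancy_p,
        "seed": fld.seed,
    }
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_lever_field(csv_path: str | Path) -> LeverField:
    """Reload a lever field written by :func:`save_lever_field`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return LeverField(
        anchors=df[["x_nm", "y_nm"]].to_numpy(float),
        mean_distance_nm=meta["mean_distance_nm"],
        occupancy_p=meta["occupancy_p"],
        seed=meta["seed"],
        side_length_nm=meta["side_length_nm"],
        in_radius_nm=meta["in_radius_nm"],
    )
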