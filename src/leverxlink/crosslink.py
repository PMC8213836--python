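"""Sequential saturation of a lever field with crosslinker molecules.

The surface model is purely geometric and sequential, with no kinetics:
molecules arrive one at a time until every binding site is consumed.  Each
DNA nanolever carries a HER2 ectodomain with two epitopes and therefore
starts with two free binding sites.  An arriving molecule first binds a
uniformly random lever with at least one free site; it then bridges to the
*closest other* lever that still has a free site and lies within the binder's
maximal reach (see :mod:`leverxlink.geometry`), or stays singly bound if none
is reachable.  A lever is *interlinked* when it is incident to at least one
bridge, and the headline readout is the fraction of interlinked levers,
replicated over independently placed surfaces and independent binding orders.

Determinism contract: for a fixed seed, the initial lever of each molecule is
chosen as ``eligible[floor(u * len(eligible))]`` where ``eligible`` is the
ascending-sorted list of levers with a free site and ``u`` the next variate of
the seeded uniform stream.  This pins the binding order to the uniform stream
alone, independent of internal data structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import CrosslinkerSpec, max_reach
from .seeding import derive_seed, spawn_rng
from .surface import LeverField, build_hex_grid, place_levers

__all__ = [
    "Molecule",
    "BindingState",
    "CrosslinkResult",
    "default_side_nm",
    "saturate_binding",
    "interlinked_fraction",
    "run_replicates",
    "crosslink_curve",
]


@dataclass(frozen=True)
class Molecule:
    molecule_id: int
    lever_a: int
    lever_b: int | None  # None when singly bound


@dataclass
class BindingState:
    """Result of saturating one lever field with one binding order."""

    n_levers: int
    free_sites: np.ndarray
    molecules: list[Molecule]
    bridges: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_bridges(self) -> int:
        return len(self.bridges)

    def sites_consumed(self) -> int:
        return sum(1 if m.lever_b is None else 2 for m in self.molecules)


@dataclass(frozen=True)
class CrosslinkResult:
    """Interlinked-lever fractions over replicate surfaces and binding orders."""

    spec_name: str
    mean_distance_nm: float
    side_nm: float
    fractions: np.ndarray  # shape (n_surfaces, n_repeats)
    n_levers: np.ndarray  # per surface
    n_molecules: np.ndarray  # shape (n_surfaces, n_repeats)
    n_bridges: np.ndarray  # shape (n_surfaces, n_repeats)
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return self.fractions.size

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())

    @property
    def sd(self) -> float:
        return float(self.fractions.std(ddof=1)) if self.fractions.size > 1 else 0.0

    @property
    def fraction_interlinked(self) -> float:
        return self.mean

    def replicate_frame(self) -> pd.DataFrame:
        ns, nr = self.fractions.shape
        return pd.DataFrame(
            {
                "spec": self.spec_name,
                "mean_distance_nm": self.mean_distance_nm,
                "surface": np.repeat(np.arange(ns), nr),
                "repeat": np.tile(np.arange(nr), ns),
                "fraction_interlinked": self.fractions.ravel(),
            }
        )


def default_side_nm(mean_distance_nm: float, reach_nm: float) -> float:
    """Surface side large enough that open-boundary effects are negligible.

    At least 2.4 um, and at least 12 times (mean distance + reach) so that the
    boundary strip of width ~reach is a small perimeter fraction.
    """
    return max(2400.0, 12.0 * (mean_distance_nm + reach_nm))


def _sorted_neighbor_lists(
    anchors: np.ndarray, reach_nm: float
) -> list[np.ndarray]:
    """Per-lever neighbors within reach, ascending by (distance, index)."""
    tree = cKDTree(anchors)
    raw = tree.query_ball_point(anchors, r=reach_nm)
    out = []
    for i, nb in enumerate(raw):
        nb = np.asarray([j for j in nb if j != i], dtype=np.intp)
        if nb.size:
            d = np.hypot(*(anchors[nb] - anchors[i]).T)
            order = np.lexsort((nb, d))  # distance first, lowest index on ties
            nb = nb[order]
        out.append(nb)
    return out


def saturate_binding(
    fld: LeverField,
    spec: CrosslinkerSpec,
    seed: int,
    initial_draw: str = "levers",
    _neighbors: Sequence[np.ndarray] | None = None,
) -> BindingState:
    """Add crosslinkers one-by-one until no free binding site remains.

    Parameters
    ----------
    fld:
        Lever field to saturate (must contain at least one lever).
    spec:
        Binder geometry; its :func:`~leverxlink.geometry.max_reach` sets the
        bridging radius.
    seed:
        Seed for the binding-order stream; identical inputs and seed give an
        identical :class:`BindingState`.
    initial_draw:
        ``"levers"`` (default) draws the first-bound lever uniformly among
        levers with at least one free site; ``"sites"`` draws uniformly among
        free *sites*, weighting doubly free levers twice.
    """
    if fld.n_levers == 0:
        raise ValueError("cannot saturate an empty lever field")
    if initial_draw not in ("levers", "sites"):
        raise ValueError("initial_draw must be 'levers' or 'sites'")
    reach = max_reach(spec)
    anchors = fld.anchors
    n = fld.n_levers
    neighbors = (
        _neighbors if _neighbors is not None else _sorted_neighbor_lists(anchors, reach)
    )
    rng = spawn_rng(seed, "binding_order")
    free = np.full(n, 2, dtype=np.int64)
    molecules: list[Molecule] = []
    bridges: set[tuple[int, int]] = set()

    while True:
        eligible = np.flatnonzero(free > 0)
        if eligible.size == 0:
            break
        u = rng.random()
        if initial_draw == "levers":
            a = int(eligible[int(u * eligible.size)])
        else:
            sites = np.repeat(eligible, free[eligible])
            a = int(sites[int(u * sites.size)])
        free[a] -= 1
        b: int | None = None
        for j in neighbors[a]:
            if free[j] > 0:
                b = int(j)
                break
        if b is not None:
            free[b] -= 1
            bridges.add((min(a, b), max(a, b)))
        molecules.append(Molecule(len(molecules), a, b))

    return BindingState(n_levers=n, free_sites=free, molecules=molecules, bridges=bridges)


def interlinked_fraction(state: BindingState) -> float:
    """Fraction of levers incident to at least one bridge.

    Chains count: any lever bridged to any other lever is interlinked, so a
    path A-B-C makes all three levers interlinked.
    """
    if state.n_levers == 0:
        raise ValueError("empty binding state")
    touched: set[int] = set()
    for a, b in state.bridges:
        touched.add(a)
        touched.add(b)
    return len(touched) / state.n_levers


def run_replicates(
    mean_distance_nm: float,
    spec: CrosslinkerSpec,
    n_surfaces: int = 10,
    n_repeats: int = 10,
    base_seed: int = 0,
    side_nm: float | None = None,
    in_radius_nm: float = 2.5,
    initial_draw: str = "levers",
) -> CrosslinkResult:
    """Replicate the saturation over fresh surfaces and fresh binding orders.

    Each surface gets an independent lever placement; each repeat on a surface
    gets an independent binding order.  The defaults (10 surfaces x 10
    repeats) give 100 replicate fractions per condition.
    """
    if n_surfaces < 1 or n_repeats < 1:
        raise ValueError("n_surfaces and n_repeats must be >= 1")
    reach = max_reach(spec)
    if side_nm is None:
        side_nm = default_side_nm(mean_distance_nm, reach)
    grid = build_hex_grid(side_nm, in_radius_nm)
    fractions = np.empty((n_surfaces, n_repeats))
    n_levers = np.empty(n_surfaces, dtype=np.int64)
    n_molecules = np.empty((n_surfaces, n_repeats), dtype=np.int64)
    n_bridges = np.empty((n_surfaces, n_repeats), dtype=np.int64)
    for s in range(n_surfaces):
        fld = place_levers(
            grid, mean_distance_nm, seed=derive_seed(base_seed, "surface", s)
        )
        n_levers[s] = fld.n_levers
        nbrs = _sorted_neighbor_lists(fld.anchors, reach) if fld.n_levers else []
        for r in range(n_repeats):
            state = saturate_binding(
                fld,
                spec,
                seed=derive_seed(base_seed, "binding", s, r),
                initial_draw=initial_draw,
                _neighbors=nbrs,
            )
            fractions[s, r] = interlinked_fraction(state)
            n_molecules[s, r] = state.n_molecules
            n_bridges[s, r] = state.n_bridges
    return CrosslinkResult(
        spec_name=spec.name,
        mean_distance_nm=float(mean_distance_nm),
        side_nm=float(side_nm),
        fractions=fractions,
        n_levers=n_levers,
        n_molecules=n_molecules,
        n_bridges=n_bridges,
        base_seed=int(base_seed),
    )


def crosslink_curve(
    specs: Sequence[CrosslinkerSpec],
    distances: Sequence[float] = (50.0, 100.0, 200.0),
    n_surfaces: int = 10,
    n_repeats: int = 10,
    base_seed: int = 0,
    side_nm: float | None = None,
    in_radius_nm: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial sweep of binder specs x mean lever distances.

    Returns ``(replicates, summary)``: a tidy per-replicate table with columns
    ``spec, mean_distance_nm, surface, repeat, fraction_interlinked`` and a
    summary table ``spec, mean_distance_nm, mean, sd, n``.
    """
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    rows = []
    for spec in specs:
        for d in distances:
            res = run_replicates(
                d,
                spec,
                n_surfaces=n_surfaces,
                n_repeats=n_repeats,
                base_seed=derive_seed(base_seed, "cell", spec.name, d),
                side_nm=side_nm,
                in_radius_nm=in_radius_nm,
            )
            rows.append(res.replicate_frame())
    replicates = pd.concat(rows, ignore_index=True)
    summary = (
        replicates.groupby(["spec", "mean_distance_nm"], sort=False)[
            "fraction_interlinked"
        ]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    return replicates, summary
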