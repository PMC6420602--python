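"""The 24-2 visual-field test grid.

The Humphrey 24-2 pattern measures differential light sensitivity at 54
locations spanning the central 24 degrees of the visual field (with a nasal
extension to 27 degrees).  Two locations fall on the physiologic blind spot
and are excluded from analysis, leaving 52 modelled locations.

Each retained location carries the angle (in degrees) at which its retinal
nerve fiber bundle enters the optic disc, per the published Garway-Heath
structure-function map.  Anatomically related locations have nearby entry
angles; the dissimilarity between adjacent locations is the circular
difference of their angles, normalized so the largest adjacent-pair
dissimilarity on the grid is exactly 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

GRID_SPACING_DEG = 6.0

__all__ = ["VFGrid", "build_grid", "dissimilarity", "circular_difference"]


def circular_difference(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Smaller arc between two angles in degrees: min(|a-b|, 360-|a-b|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class VFGrid:
    """The 24-2 lattice restricted to its 52 non-blind-spot locations.

    Attributes
    ----------
    location_id : (54,) int array, standard HFA reading order (1..54).
    x, y : (54,) float arrays, degrees of visual angle, right-eye orientation.
    is_blind_spot : (54,) bool array; exactly two True entries.
    gh_angle : (54,) float array, Garway-Heath optic-disc entry angle in
        [0, 360); NaN at the blind spot.
    retained_ids : (52,) int array of analyzed location ids.
    edge_i, edge_j : (E,) int arrays of adjacent retained-location indices
        (0-based positions into ``retained_ids``), with edge_i < edge_j.
    edge_z : (E,) float array of normalized dissimilarities in [0, 1].
    adjacency_rule : "queen" or "rook".
    """

    location_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    is_blind_spot: np.ndarray
    gh_angle: np.ndarray
    retained_ids: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_z: np.ndarray
    adjacency_rule: str
    _index_of: dict = field(repr=False, default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    def index_of(self, location_id: int) -> int:
        """0-based position of a retained location id; blind spot -> error."""
        try:
            return self._index_of[int(location_id)]
        except KeyError:
            raise ValueError(
                f"location {location_id} is not a retained grid location "
                "(blind spot or out of range)"
            ) from None

    @property
    def adjacency(self) -> set[tuple[int, int]]:
        """Unordered adjacent pairs as (location_id, location_id), id_i < id_j."""
        ids = self.retained_ids
        return {
            (int(ids[i]), int(ids[j])) for i, j in zip(self.edge_i, self.edge_j)
        }


def _load_packaged_table() -> pd.DataFrame:
    ref = importlib.resources.files("vfprog.data").joinpath("garway_heath_24_2.csv")
    try:
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
    except FileNotFoundError as exc:  # pragma: no cover - packaging error
        raise RuntimeError(
            "packaged Garway-Heath angle table is missing; reinstall vfprog"
        ) from exc
    required = {"location_id", "x", "y", "is_blind_spot", "gh_angle"}
    if not required.issubset(table.columns):
        raise RuntimeError(
            f"packaged grid table lacks columns {sorted(required - set(table.columns))}"
        )
    return table


def _adjacent(dx: np.ndarray, dy: np.ndarray, rule: str) -> np.ndarray:
    if rule == "queen":
        return (np.maximum(dx, dy) <= GRID_SPACING_DEG) & ((dx + dy) > 0)
    if rule == "rook":
        return (dx + dy == GRID_SPACING_DEG) & (np.minimum(dx, dy) == 0)
    raise ValueError(f"adjacency_rule must be 'queen' or 'rook', got {rule!r}")


def grid_from_table(table: pd.DataFrame, adjacency_rule: str = "queen") -> VFGrid:
    """Build a :class:`VFGrid` from an explicit location table.

    Row order is irrelevant: the table is sorted by ``location_id``.  Used by
    :func:`build_grid` with the packaged table, and directly by tests that
    substitute synthetic angles.
    """
    table = table.sort_values("location_id").reset_index(drop=True)
    loc = table["location_id"].to_numpy(dtype=int)
    x = table["x"].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    blind = table["is_blind_spot"].to_numpy(dtype=bool)
    angle = table["gh_angle"].to_numpy(dtype=float)

    if len(loc) != 54 or not np.array_equal(loc, np.arange(1, 55)):
        raise ValueError("grid table must contain location_id 1..54 exactly once each")
    if blind.sum() != 2:
        raise ValueError("grid table must flag exactly 2 blind-spot locations")
    keep = ~blind
    if np.isnan(angle[keep]).any():
        raise ValueError("gh_angle missing for a retained location")
    if ((angle[keep] < 0) | (angle[keep] >= 360)).any():
        raise ValueError("gh_angle must lie in [0, 360)")

    retained_ids = loc[keep]
    rx, ry, rangle = x[keep], y[keep], angle[keep]
    dx = np.abs(rx[:, None] - rx[None, :])
    dy = np.abs(ry[:, None] - ry[None, :])
    adj = _adjacent(dx, dy, adjacency_rule)
    ei, ej = np.nonzero(np.triu(adj, k=1))

    n = len(retained_ids)
    graph = csr_matrix((np.ones(len(ei)), (ei, ej)), shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp != 1:
        raise ValueError("retained-location adjacency graph is not connected")

    raw = circular_difference(rangle[ei], rangle[ej])
    zmax = raw.max()
    if zmax <= 0:
        raise ValueError("all adjacent Garway-Heath angles identical; cannot normalize")
    z = raw / zmax

    return VFGrid(
        location_id=loc,
        x=x,
        y=y,
        is_blind_spot=blind,
        gh_angle=angle,
        retained_ids=retained_ids,
        edge_i=ei,
        edge_j=ej,
        edge_z=z,
        adjacency_rule=adjacency_rule,
        _index_of={int(l): k for k, l in enumerate(retained_ids)},
    )


def build_grid(adjacency_rule: str = "queen") -> VFGrid:
    """Construct the standard 24-2 grid from the packaged angle table.

    Parameters
    ----------
    adjacency_rule : "queen" (default; 8-neighbour on the 6-degree lattice)
        or "rook" (edge-sharing neighbours only).
    """
    return grid_from_table(_load_packaged_table(), adjacency_rule)


def dissimilarity(grid: VFGrid) -> dict[tuple[int, int], float]:
    """Normalized Garway-Heath dissimilarity per adjacent pair.

    Returns a symmetric mapping: both (i, j) and (j, i) are present.
    """
    ids = grid.retained_ids
    out: dict[tuple[int, int], float] = {}
    for i, j, z in zip(grid.edge_i, grid.edge_j, grid.edge_z):
        a, b = int(ids[i]), int(ids[j])
        out[(a, b)] = float(z)
        out[(b, a)] = float(z)
    return out
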