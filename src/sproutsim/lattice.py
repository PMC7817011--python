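"""Hexagonal lattice geometry.

The simulation domain is covered by a uniform lattice of non-overlapping
regular hexagonal voxels of width ``h`` (flat-to-flat distance, in um).
Voxels are pointy-top hexagons arranged in row-offset ("odd-r") order, so
each interior voxel has six neighbours whose centres sit at distance ``h``
at angles ``0, +-pi/3, +-2pi/3, pi``.  The hexagon edge length is
``a = h / sqrt(3)``.

Cells interact non-locally: a cell in voxel ``i`` sees every voxel whose
hexagon overlaps a disc of some interaction radius centred on ``q_i``, with
a weight equal to the overlapped area fraction of that voxel.  Those
overlap weights drive both the juxtacrine signalling average (radius
``R_s``) and the neighbourhood-occupancy measure (radius ``R_c``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "DIRECTIONS",
    "Direction",
    "HexLattice",
    "angle_interval",
    "direction_labels",
    "overlap_weights",
]

_SQRT3 = math.sqrt(3.0)

# Direction order is fixed throughout the package: index 0..5.
_LABELS = ("r", "ur", "ul", "l", "dl", "dr")
_ANGLES = (0.0, math.pi / 3, 2 * math.pi / 3, math.pi, -2 * math.pi / 3, -math.pi / 3)


@dataclass(frozen=True)
class Direction:
    """One of the six migration directions of the hexagonal lattice."""

    index: int
    label: str
    angle: float

    @property
    def unit_vector(self) -> tuple[float, float]:
        return (math.cos(self.angle), math.sin(self.angle))

    @property
    def angle_interval(self) -> tuple[float, float]:
        return angle_interval(self)

    @property
    def opposite(self) -> "Direction":
        return DIRECTIONS[(self.index + 3) % 6]


DIRECTIONS: tuple[Direction, ...] = tuple(
    Direction(i, lab, ang) for i, (lab, ang) in enumerate(zip(_LABELS, _ANGLES))
)


def direction_labels() -> tuple[str, ...]:
    return _LABELS


def angle_interval(s: Direction | int | str) -> tuple[float, float]:
    """Half-open polarity-angle interval ``[phi_min, phi_max)`` of direction ``s``.

    Each migration direction owns an interval of width ``pi/3`` centred on its
    axis; the right direction gets ``[-pi/6, pi/6)`` and the six intervals
    partition ``[-pi, pi)`` (the interval of ``l`` wraps through ``+-pi``).
    """
    s = as_direction(s)
    lo = s.angle - math.pi / 6
    hi = s.angle + math.pi / 6
    return (lo, hi)


def as_direction(s: Direction | int | str) -> Direction:
    if isinstance(s, Direction):
        return s
    if isinstance(s, str):
        return DIRECTIONS[_LABELS.index(s)]
    return DIRECTIONS[int(s)]


# Offset steps (dcol, drow) for even rows and odd rows, in direction order.
_STEPS_EVEN = ((1, 0), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1))
_STEPS_ODD = ((1, 0), (1, 1), (0, 1), (-1, 0), (0, -1), (1, -1))


@dataclass
class HexLattice:
    """Uniform pointy-top hexagonal lattice of ``n_x`` columns by ``n_y`` rows.

    Voxel ``(col, row)`` maps to the flat index ``row * n_x + col``.  Odd rows
    are shifted right by ``h/2`` so that neighbouring centres are exactly
    ``h`` apart.
    """

    n_x: int
    n_y: int
    h: float = 10.0
    _neighbors: np.ndarray = field(init=False, repr=False)
    _centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("lattice dimensions must be positive")
        cols = np.arange(self.n_x)
        rows = np.arange(self.n_y)
        cc, rr = np.meshgrid(cols, rows)  # shape (n_y, n_x)
        x = self.h * (cc + 0.5 * (rr % 2))
        y = (_SQRT3 / 2.0) * self.h * rr
        self._centers = np.stack([x.ravel(), y.ravel()], axis=1)
        self._neighbors = self._build_neighbors()

    # -- basic properties ---------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y

    @property
    def a(self) -> float:
        """Hexagon edge length; ``h = sqrt(3) * a``."""
        return self.h / _SQRT3

    @property
    def voxel_area(self) -> float:
        return (_SQRT3 / 2.0) * self.h**2

    @property
    def centers(self) -> np.ndarray:
        """Array of shape (n_voxels, 2) of voxel centre coordinates in um."""
        return self._centers

    @property
    def neighbor_table(self) -> np.ndarray:
        """Int array (n_voxels, 6); entry -1 marks an off-lattice direction."""
        return self._neighbors

    # -- indexing -----------------------------------------------------------
    def index(self, col: int, row: int) -> int:
        if not (0 <= col < self.n_x and 0 <= row < self.n_y):
            raise IndexError(f"voxel ({col}, {row}) outside lattice")
        return row * self.n_x + col

    def colrow(self, i: int) -> tuple[int, int]:
        self._check(i)
        return (i % self.n_x, i // self.n_x)

    def _check(self, i: int) -> None:
        if not (0 <= i < self.n_voxels):
            raise IndexError(f"voxel index {i} outside lattice")

    def _build_neighbors(self) -> np.ndarray:
        nb = np.full((self.n_voxels, 6), -1, dtype=np.int64)
        for row in range(self.n_y):
            steps = _STEPS_ODD if row % 2 else _STEPS_EVEN
            for col in range(self.n_x):
                i = row * self.n_x + col
                for s, (dc, dr) in enumerate(steps):
                    c2, r2 = col + dc, row + dr
                    if 0 <= c2 < self.n_x and 0 <= r2 < self.n_y:
                        nb[i, s] = r2 * self.n_x + c2
        return nb

    def neighbor(self, i: int, s: Direction | int | str) -> int | None:
        """Index of the voxel adjacent to ``i`` in direction ``s`` (None off-lattice)."""
        self._check(i)
        j = self._neighbors[i, as_direction(s).index]
        return None if j < 0 else int(j)

    def hexagon(self, i: int) -> Polygon:
        """Shapely polygon of voxel ``i`` (pointy-top regular hexagon)."""
        cx, cy = self._centers[i]
        a = self.a
        pts = [
            (cx + a * math.cos(t), cy + a * math.sin(t))
            for t in (math.pi / 2 + k * math.pi / 3 for k in range(6))
        ]
        return Polygon(pts)

    def interior_mask(self) -> np.ndarray:
        return (self._neighbors >= 0).all(axis=1)


def overlap_weights(lattice: HexLattice, i: int, R: float) -> dict[int, float]:
    """Area-overlap weights of the disc of radius ``R`` (um) centred on voxel ``i``.

    Returns ``{j: |v_j intersect B_R(i)| / |v_j|}`` for every voxel with a
    non-zero intersection (including ``j = i`` itself, which callers building
    the signalling neighbourhood drop).  Intersection areas are computed by
    polygon clipping against a finely discretised circle; the discretisation
    error is far below the 1e-3 level the weights are consumed at.
    """
    if R <= 0:
        raise ValueError("interaction radius must be positive")
    lattice._check(i)
    cx, cy = lattice.centers[i]
    disc = Point(cx, cy).buffer(R, quad_segs=128)
    area = lattice.voxel_area
    # Only voxels whose centre lies within R + circumradius can intersect.
    reach = R + lattice.a + lattice.h * 1e-9
    d2 = ((lattice.centers - (cx, cy)) ** 2).sum(axis=1)
    out: dict[int, float] = {}
    for j in np.flatnonzero(d2 <= reach**2):
        w = lattice.hexagon(int(j)).intersection(disc).area / area
        if w > 1e-12:
            out[int(j)] = min(1.0, float(w))
    return out


@lru_cache(maxsize=32)
def _cached_weights(n_x: int, n_y: int, h: float, R: float):
    """CSR-form overlap weights for all voxels, self excluded; cached per lattice."""
    lat = HexLattice(n_x, n_y, h)
    indptr = np.zeros(lat.n_voxels + 1, dtype=np.int64)
    idx: list[int] = []
    wts: list[float] = []
    for i in range(lat.n_voxels):
        w = overlap_weights(lat, i, R)
        w.pop(i, None)
        for j in sorted(w):
            idx.append(j)
            wts.append(w[j])
        indptr[i + 1] = len(idx)
    return indptr, np.asarray(idx, dtype=np.int64), np.asarray(wts, dtype=np.float64)


def weights_csr(lattice: HexLattice, R: float):
    """(indptr, indices, weights) of the self-excluded overlap neighbourhood."""
    return _cached_weights(lattice.n_x, lattice.n_y, lattice.h, float(R))
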