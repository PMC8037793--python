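"""Idealized coiled-aneurysm geometry on a Cartesian staggered grid.

The flow domain is a 2D straight parent-vessel channel with a circular
side-wall dome attached through a neck opening.  The patient-specific
surface the published hemodynamic values were obtained on is not
available, so this idealized geometry is the stand-in on which the
porous-dome model is exercised; results on it are interpreted
qualitatively (trends over packing density), never as value-level
reproductions.

Cells are classified as fluid (channel lumen), porous_dome (the coiled
sac), or solid; the x = 0 channel boundary is the inlet and x = L the
outlet.  Velocity components live on cell faces (MAC layout), pressure at
cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

SOLID = 0
FLUID = 1
POROUS = 2

ROLE_NAMES = {SOLID: "solid", FLUID: "fluid", POROUS: "porous_dome"}

MIN_CELLS_PER_DIAMETER = 16


@dataclass(frozen=True)
class DomainSpec:
    """Idealized parent-vessel + side-dome geometry (all lengths in m)."""

    parent_diameter: float
    parent_length: float
    dome_radius: float  # 0 => plain channel, no dome
    neck_width: float
    grid_spacing: float
    dome_center_x: Optional[float] = None  # default: mid-channel
    dimensionality: int = 2
    porous_channel: bool = False  # packed-bed validation: whole lumen porous

    def __post_init__(self) -> None:
        if self.dimensionality != 2:
            raise NotImplementedError("only the 2D planar geometry is implemented")
        for name in ("parent_diameter", "parent_length", "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dome_radius < 0 or self.neck_width < 0:
            raise ValueError("dome_radius and neck_width must be non-negative")
        if self.dome_radius > 0 and self.neck_width > 2.0 * self.dome_radius:
            raise ValueError(
                f"neck_width {self.neck_width} exceeds dome diameter "
                f"{2.0 * self.dome_radius}"
            )
        cells_per_d = self.parent_diameter / self.grid_spacing
        if cells_per_d < MIN_CELLS_PER_DIAMETER:
            required = self.parent_diameter / MIN_CELLS_PER_DIAMETER
            raise ValueError(
                f"under-resolved grid: {cells_per_d:.1f} cells per parent diameter "
                f"(need >= {MIN_CELLS_PER_DIAMETER}); use grid_spacing <= {required:.3e} m"
            )


@dataclass
class Domain:
    """Discrete domain: cell roles, masks, and wall-face bookkeeping.

    Wall faces are stored as integer arrays of (cell_i, cell_j, side) with
    side in {0: -x, 1: +x, 2: -y, 3: +y} naming the solid neighbour
    direction seen from the flow cell.
    """

    spec: DomainSpec
    nx: int
    ny: int
    h: float
    role: np.ndarray  # (nx, ny) int
    ny_channel: int  # channel occupies j < ny_channel
    wall_faces_artery: np.ndarray  # (n, 3)
    wall_faces_dome: np.ndarray  # (n, 3)
    neck_face_i: np.ndarray  # x-indices of v-faces forming the neck plane

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.role == FLUID

    @property
    def porous_mask(self) -> np.ndarray:
        return self.role == POROUS

    @property
    def active_mask(self) -> np.ndarray:
        return self.role != SOLID

    @property
    def inlet_rows(self) -> np.ndarray:
        return np.flatnonzero(self.role[0, :] != SOLID)

    def cell_volume(self) -> float:
        # per unit depth
        return self.h * self.h


# side codes: solid neighbour direction from the flow cell
SIDE_XM, SIDE_XP, SIDE_YM, SIDE_YP = 0, 1, 2, 3
SIDE_OFFSETS = {SIDE_XM: (-1, 0), SIDE_XP: (1, 0), SIDE_YM: (0, -1), SIDE_YP: (0, 1)}


def build_domain(spec: DomainSpec) -> Domain:
    """Rasterize the channel + dome geometry onto the staggered grid.

    Raises if the dome is disconnected from the lumen (no open neck cells)
    — a sac with no neck would make every porous-dome observable
    meaningless.
    """
    h = spec.grid_spacing
    nx = int(round(spec.parent_length / h))
    ny_channel = int(round(spec.parent_diameter / h))

    has_dome = spec.dome_radius > 0
    if has_dome:
        half_w = spec.neck_width / 2.0
        stalk = float(np.sqrt(max(spec.dome_radius**2 - half_w**2, 0.0)))
        cy = ny_channel * h + stalk  # dome center height above channel floor
        top = cy + spec.dome_radius
        ny = int(np.ceil(top / h)) + 1
        cx = spec.dome_center_x if spec.dome_center_x is not None else spec.parent_length / 2.0
    else:
        ny = ny_channel
        cx = cy = 0.0

    role = np.full((nx, ny), SOLID, dtype=np.int8)
    role[:, :ny_channel] = POROUS if spec.porous_channel else FLUID

    if has_dome:
        xc = (np.arange(nx) + 0.5) * h
        yc = (np.arange(ny) + 0.5) * h
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        in_disk = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.dome_radius**2
        dome = in_disk & (Y > ny_channel * h)
        role[dome] = POROUS

        # connectivity: porous cells in the row just above the channel open
        # the neck; require at least one, and require the porous region to
        # be a single component reachable from the neck row.
        neck_row = ny_channel
        neck_cols = np.flatnonzero(role[:, neck_row] == POROUS)
        if neck_cols.size == 0:
            raise ValueError("dome disconnected from lumen: no open neck cells")
        reached = _flood_fill(role == POROUS, [(int(i), neck_row) for i in neck_cols])
        if not np.array_equal(reached, role == POROUS):
            raise ValueError("porous dome is not a single connected component")
        neck_face_i = neck_cols
    else:
        neck_face_i = np.array([], dtype=int)

    wall_artery, wall_dome = _collect_wall_faces(role, ny_channel)
    return Domain(
        spec=spec,
        nx=nx,
        ny=ny,
        h=h,
        role=role,
        ny_channel=ny_channel,
        wall_faces_artery=wall_artery,
        wall_faces_dome=wall_dome,
        neck_face_i=neck_face_i,
    )


def _flood_fill(mask: np.ndarray, seeds) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    stack = [s for s in seeds if mask[s]]
    for s in stack:
        out[s] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < mask.shape[0] and 0 <= jj < mask.shape[1]:
                if mask[ii, jj] and not out[ii, jj]:
                    out[ii, jj] = True
                    stack.append((ii, jj))
    return out


def _collect_wall_faces(role: np.ndarray, ny_channel: int):
    """List solid-adjacent faces of flow cells, split artery vs dome."""
    nx, ny = role.shape
    artery, dome = [], []
    for i in range(nx):
        for j in range(ny):
            r = role[i, j]
            if r == SOLID:
                continue
            for side, (di, dj) in SIDE_OFFSETS.items():
                ii, jj = i + di, j + dj
                if 0 <= ii < nx and 0 <= jj < ny:
                    solid_nb = role[ii, jj] == SOLID
                else:
                    # domain boundary: y-extremes are walls; x-extremes are
                    # inlet/outlet for channel rows, walls otherwise
                    if dj != 0:
                        solid_nb = True
                    else:
                        solid_nb = j >= ny_channel
                if solid_nb:
                    (dome if r == POROUS else artery).append((i, j, side))
    to_arr = lambda lst: (
        np.array(lst, dtype=int) if lst else np.empty((0, 3), dtype=int)
    )
    return to_arr(artery), to_arr(dome)
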