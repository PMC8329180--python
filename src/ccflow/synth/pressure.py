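"""Pressure-gradient perfusion model.

The choriocapillaris is treated as a thin 2-D porous sheet: arterioles
inject flow at points, venules withdraw it, and the pressure field solves
the discrete Laplace equation with those point sources/sinks and zero-flux
(Neumann) boundaries. Velocity is the negative pressure gradient (Darcy
flow, up to a mobility constant). Each pixel is assigned to the arteriole
whose basin it lies in by tracing the flow streamline backwards (discrete
steepest-ascent on pressure), accumulating a transit time along the way.
Pixels near basin boundaries sit close to stagnation lines, so their
transit times are naturally the longest — these are the slow inter-lobule
zones that fill last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import DegenerateMapError
from ..geometry import FieldGeometry
from .vessels import VascularMap

#: ownership value for pixels that could not be traced to an arteriole
UNPERFUSED = -1

# floor on speed (mm/s) when accumulating transit time; prevents division
# blow-up exactly on stagnation points while keeping boundary-zone transit
# times much longer than intra-lobule ones
_SPEED_FLOOR = 1e-6


@dataclass
class PerfusionField:
    """Solved perfusion state on the pixel grid.

    Attributes
    ----------
    pressure : (ny, nx) float array, zero-mean gauge
    velocity : (2, ny, nx) float array, (vx, vy) in mm/s
    transit_time : (ny, nx) float array, seconds from the owning arteriole
        (``inf`` where unperfused)
    ownership : (ny, nx) int array, arteriole index or ``UNPERFUSED``
    """

    pressure: np.ndarray
    velocity: np.ndarray
    transit_time: np.ndarray
    ownership: np.ndarray
    vascular_map: VascularMap
    geometry: FieldGeometry
    mobility: float

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity[0], self.velocity[1])


def _neumann_laplacian(ny: int, nx: int, hx: float, hy: float) -> sp.csr_matrix:
    """5-point Laplacian with zero-flux boundaries, in row-major ordering."""
    ex = np.ones(nx)
    ey = np.ones(ny)
    dx = sp.diags([ex[:-1], ex[:-1]], [-1, 1], shape=(nx, nx), format="lil")
    dy = sp.diags([ey[:-1], ey[:-1]], [-1, 1], shape=(ny, ny), format="lil")
    # Neumann: diagonal equals number of existing neighbours
    lap_x = dx - sp.diags(np.asarray(dx.sum(axis=1)).ravel())
    lap_y = dy - sp.diags(np.asarray(dy.sum(axis=1)).ravel())
    return (
        sp.kron(sp.eye(ny), lap_x) / hx**2 + sp.kron(lap_y, sp.eye(nx)) / hy**2
    ).tocsr()


def solve_pressure(
    vmap: VascularMap,
    geometry: FieldGeometry,
    mobility: float = 0.55,
) -> PerfusionField:
    """Solve the pressure field and derive velocity, ownership, transit time.

    The linear system is ``lap(p) = -s`` where ``s`` is the source density
    (vessel strength spread over one pixel). The Neumann problem is singular
    up to a constant; the gauge is fixed by pinning one node and then
    removing the mean. Consistency requires the map to be flux balanced.

    Parameters
    ----------
    mobility : float
        Darcy mobility converting pressure gradient (pressure units/mm)
        into velocity (mm/s). The default is calibrated so that, with the
        package's default field and vessel strengths, a lobule core fills
        within roughly a second while boundary zones lag by several.
    """
    strengths = np.concatenate([vmap.arteriole_strengths, vmap.venule_strengths])
    if np.all(strengths == 0):
        raise DegenerateMapError("all vessel strengths are zero")
    if abs(vmap.net_flux()) > 1e-9 * np.abs(strengths).sum():
        raise DegenerateMapError("vascular map is not flux balanced")

    ny, nx = geometry.shape
    hx = geometry.width_mm / nx
    hy = geometry.height_mm / ny

    rhs = np.zeros(ny * nx)
    positions = np.vstack([vmap.arterioles, vmap.venules])
    vessel_pixels = []
    for pos, q in zip(positions, strengths):
        r, c = geometry.mm_to_pixel(pos)
        rhs[r * nx + c] -= q / (hx * hy)
        vessel_pixels.append((r, c))

    lap = _neumann_laplacian(ny, nx, hx, hy).tolil()
    # pin node 0 to remove the constant null space; its original equation is
    # implied by the others because rows and rhs both sum to zero
    lap[0, :] = 0.0
    lap[0, 0] = 1.0
    rhs = rhs.copy()
    rhs[0] = 0.0
    p = spla.spsolve(lap.tocsc(), rhs)
    p = (p - p.mean()).reshape(ny, nx)

    dp_dy, dp_dx = np.gradient(p, hy, hx)
    velocity = np.stack([-dp_dx * mobility, -dp_dy * mobility])

    ownership, transit = _trace_ownership(
        p, velocity, vessel_pixels[: vmap.n_arterioles], hx, hy
    )
    return PerfusionField(
        pressure=p,
        velocity=velocity,
        transit_time=transit,
        ownership=ownership,
        vascular_map=vmap,
        geometry=geometry,
        mobility=mobility,
    )


def _trace_ownership(pressure, velocity, arteriole_pixels, hx, hy):
    """Backward streamline tracing by discrete steepest ascent.

    Each pixel points at its highest-pressure 8-neighbour; following those
    pointers uphill reaches a local pressure maximum, which by the maximum
    principle is an arteriole pixel. Transit time accumulates hop by hop as
    hop length over the local speed.
    """
    ny, nx = pressure.shape
    padded = np.full((ny + 2, nx + 2), -np.inf)
    padded[1:-1, 1:-1] = pressure

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nb_p = np.stack(
        [padded[1 + dy : 1 + dy + ny, 1 + dx : 1 + dx + nx] for dy, dx in offsets]
    )
    best = np.argmax(nb_p, axis=0)
    best_p = np.take_along_axis(nb_p, best[None], axis=0)[0]
    has_parent = best_p > pressure

    speed = np.hypot(velocity[0], velocity[1])
    off = np.array(offsets, dtype=float)
    hop_len = np.hypot(off[:, 1] * hx, off[:, 0] * hy)  # mm

    ownership = np.full((ny, nx), UNPERFUSED, dtype=np.int32)
    transit = np.full((ny, nx), np.inf)
    for idx, (r, c) in enumerate(arteriole_pixels):
        ownership[r, c] = idx
        transit[r, c] = 0.0

    order = np.argsort(pressure, axis=None)[::-1]
    rows, cols = np.unravel_index(order, pressure.shape)
    dr = off[:, 0].astype(int)
    dc = off[:, 1].astype(int)
    for r, c in zip(rows, cols):
        if ownership[r, c] != UNPERFUSED:
            continue
        if not has_parent[r, c]:
            continue  # non-arteriole local max: leave unperfused
        k = best[r, c]
        pr, pc = r + dr[k], c + dc[k]
        if ownership[pr, pc] == UNPERFUSED:
            continue
        v_mid = max(0.5 * (speed[r, c] + speed[pr, pc]), _SPEED_FLOOR)
        ownership[r, c] = ownership[pr, pc]
        transit[r, c] = transit[pr, pc] + hop_len[k] / v_mid
    return ownership, transit


def trace_streamline(
    field: PerfusionField, start_rc: tuple[int, int], max_steps: int = 100_000
) -> np.ndarray:
    """Follow the discrete ascent path from ``start_rc`` to its arteriole.

    Returns the (n, 2) array of (row, col) pixels visited, ending at the
    owning arteriole pixel (or at a local maximum if unperfused).
    """
    pressure = field.pressure
    ny, nx = pressure.shape
    path = [start_rc]
    r, c = start_rc
    for _ in range(max_steps):
        window = pressure[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        k = np.argmax(window)
        wr, wc = np.unravel_index(k, window.shape)
        nr, nc = max(r - 1, 0) + wr, max(c - 1, 0) + wc
        if (nr, nc) == (r, c) or pressure[nr, nc] <= pressure[r, c]:
            break
        r, c = nr, nc
        path.append((r, c))
    return np.array(path)
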