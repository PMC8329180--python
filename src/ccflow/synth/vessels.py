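"""Random arteriole/venule placement.

Feeding arterioles and draining venules of the choriocapillaris are not
arranged in a fixed lattice; they are scattered irregularly. This module
places them by seeded rejection sampling with a minimum pairwise spacing,
and assigns equal-magnitude strengths so that total inflow balances total
outflow (a requirement for the Neumann pressure solve to be consistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import substream
from ..errors import SpacingInfeasibleError
from ..geometry import FieldGeometry

_MAX_ATTEMPTS_PER_VESSEL = 2000


@dataclass(frozen=True)
class VascularMap:
    """Arteriole (source) and venule (sink) layout.

    ``arterioles`` and ``venules`` are ``(n, 2)`` arrays of (x_mm, y_mm)
    positions; ``arteriole_strengths`` are positive, ``venule_strengths``
    negative, and they sum to zero (flux balance).
    """

    arterioles: np.ndarray
    venules: np.ndarray
    arteriole_strengths: np.ndarray
    venule_strengths: np.ndarray
    seed: int

    @property
    def n_arterioles(self) -> int:
        return len(self.arterioles)

    @property
    def n_venules(self) -> int:
        return len(self.venules)

    def net_flux(self) -> float:
        return float(self.arteriole_strengths.sum() + self.venule_strengths.sum())


def place_vessels(
    geometry: FieldGeometry,
    n_arterioles: int,
    n_venules: int,
    min_spacing_um: float,
    seed: int,
    margin_mm: float = 0.05,
) -> VascularMap:
    """Place arterioles and venules by seeded rejection sampling.

    Positions are uniform over the field (inset by ``margin_mm``) subject to
    all pairwise distances being at least ``min_spacing_um``. Arterioles get
    strength +1 each; venule strengths are ``-n_arterioles / n_venules`` so
    net flux is exactly zero.

    Raises
    ------
    SpacingInfeasibleError
        If a conforming layout cannot be found within the attempt budget.
    """
    if n_arterioles < 1 or n_venules < 1:
        raise ValueError("need at least one arteriole and one venule")
    if min_spacing_um < 0:
        raise ValueError("min_spacing_um must be non-negative")

    n_total = n_arterioles + n_venules
    spacing_mm = min_spacing_um / 1000.0
    # quick area feasibility check: disks of radius spacing/2 must fit
    usable = (geometry.width_mm - 2 * margin_mm) * (geometry.height_mm - 2 * margin_mm)
    if n_total * np.pi * (spacing_mm / 2) ** 2 > usable:
        raise SpacingInfeasibleError(
            f"{n_total} vessels with {min_spacing_um} um spacing cannot fit "
            f"in a {geometry.width_mm} x {geometry.height_mm} mm field"
        )

    rng = substream(seed, "place_vessels")
    placed = np.empty((n_total, 2))
    n_placed = 0
    attempts = 0
    budget = _MAX_ATTEMPTS_PER_VESSEL * n_total
    while n_placed < n_total:
        if attempts >= budget:
            raise SpacingInfeasibleError(
                f"failed to place {n_total} vessels with spacing >= "
                f"{min_spacing_um} um after {budget} attempts"
            )
        attempts += 1
        x = rng.uniform(margin_mm, geometry.width_mm - margin_mm)
        y = rng.uniform(margin_mm, geometry.height_mm - margin_mm)
        if n_placed:
            d2 = ((placed[:n_placed] - [x, y]) ** 2).sum(axis=1)
            if d2.min() < spacing_mm**2:
                continue
        placed[n_placed] = (x, y)
        n_placed += 1

    arterioles = placed[:n_arterioles].copy()
    venules = placed[n_arterioles:].copy()
    a_strength = np.ones(n_arterioles)
    v_strength = np.full(n_venules, -n_arterioles / n_venules)
    return VascularMap(arterioles, venules, a_strength, v_strength, seed=int(seed))
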