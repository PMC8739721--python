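"""Cumulative BED maps: voxel-wise summation and isodose level sets.

BED is additive across courses under the linear-quadratic model, so per-course
BED grids on a common reference geometry sum voxel by voxel into a composite.
Summing BED maps computed at different alpha/beta ratios is meaningless and is
refused. Voxels excluded (NaN) in any input stay excluded in the composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bed import AlphaBetaRatio, BEDGrid
from .dose_io import StructureMask
from .geometry import GridGeometry

__all__ = ["CompositeBEDGrid", "sum_bed", "composite_isodose"]


@dataclass
class CompositeBEDGrid:
    """Voxel-wise cumulative BED (Gy) over two or more courses."""

    geometry: GridGeometry
    values: np.ndarray
    alpha_beta: AlphaBetaRatio
    source_courses: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.geometry.dims:
            raise ValueError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )
        self.source_courses = tuple(self.source_courses)

    @property
    def evaluated(self) -> np.ndarray:
        return np.isfinite(self.values)


def sum_bed(maps: Sequence[BEDGrid]) -> CompositeBEDGrid:
    """Sum >= 2 BED grids on identical geometry into a composite BED grid.

    Inputs must share geometry exactly (resample/warp beforehand) and the
    same alpha/beta. Summation order is fixed (input order) so results are
    bit-reproducible; excluded voxels propagate (NaN + x = NaN).
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("sum_bed requires at least 2 BED maps")
    ref = maps[0]
    for m in maps[1:]:
        if float(m.alpha_beta) != float(ref.alpha_beta):
            raise ValueError(
                "refusing to sum BED maps with different alpha/beta "
                f"({float(m.alpha_beta)} Gy vs {float(ref.alpha_beta)} Gy): "
                "BEDs at different alpha/beta are not commensurable"
            )
        if not m.geometry.same_as(ref.geometry):
            raise ValueError(
                "BED maps are on different geometries; resample/warp them onto "
                "a common reference grid before summation"
            )
    total = maps[0].values.copy()
    for m in maps[1:]:
        total = total + m.values
    labels = tuple(lbl for m in maps for lbl in m.source_courses)
    return CompositeBEDGrid(
        geometry=ref.geometry, values=total, alpha_beta=ref.alpha_beta,
        source_courses=labels,
    )


def composite_isodose(
    composite: CompositeBEDGrid, levels: Sequence[float]
) -> dict[float, StructureMask]:
    """Level-set masks ``{voxel : BED >= L}`` for each requested level.

    Levels must be non-negative and sorted ascending; the returned masks are
    nested (higher level is a subset of lower level). Excluded voxels are in
    no mask; level 0 returns the full evaluated support.
    """
    levels = [float(v) for v in levels]
    if any(v < 0 for v in levels):
        raise ValueError("isodose levels must be >= 0 Gy")
    if sorted(levels) != levels:
        raise ValueError("isodose levels must be sorted ascending")
    evaluated = composite.evaluated
    out: dict[float, StructureMask] = {}
    for lv in levels:
        occ = evaluated & (composite.values >= lv)
        out[lv] = StructureMask(
            geometry=composite.geometry, occupancy=occ, name=f"BED>={lv:g}Gy"
        )
    return out
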