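"""Voxel-wise biologically effective dose (BED) conversion.

Under the linear-quadratic model, a course of ``n`` equal fractions each
delivering physical dose ``d`` to a voxel has

    BED = n * d * (1 + d / (alpha/beta))

where alpha/beta is the tissue-specific LQ parameter in Gy (3 Gy for
late-responding normal tissue by default). The per-fraction dose at a voxel
is derived from the stored course total as ``d = D_total / n``, i.e. every
fraction is assumed to deliver the same spatial distribution.

BED makes courses with different fraction sizes commensurable: BED maps are
additive across courses, unlike nominal physical dose. Voxels excluded from
normal-tissue evaluation (e.g. tumor) are carried as NaN and drop out of all
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_io import DoseGrid, StructureMask, TreatmentCourse
from .geometry import GridGeometry

__all__ = ["AlphaBetaRatio", "BEDGrid", "voxel_bed", "bed_map", "eqd2_from_bed"]

#: Default alpha/beta for late-responding normal tissue, Gy.
NORMAL_TISSUE_ALPHA_BETA = 3.0


@dataclass(frozen=True)
class AlphaBetaRatio:
    """The LQ-model alpha/beta ratio in Gy; strictly positive."""

    value: float = NORMAL_TISSUE_ALPHA_BETA

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", float(self.value))
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"alpha/beta must be finite and > 0 Gy, got {self.value}")

    def __float__(self) -> float:
        return self.value


def _as_alpha_beta(alpha_beta: AlphaBetaRatio | float) -> AlphaBetaRatio:
    if isinstance(alpha_beta, AlphaBetaRatio):
        return alpha_beta
    return AlphaBetaRatio(float(alpha_beta))


@dataclass
class BEDGrid:
    """A 3-D raster of BED (Gy) tagged with the alpha/beta used.

    Excluded voxels (not evaluated, e.g. tumor) are NaN.
    """

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
        self.alpha_beta = _as_alpha_beta(self.alpha_beta)
        self.source_courses = tuple(self.source_courses)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("BED values must be >= 0 Gy")

    @property
    def evaluated(self) -> np.ndarray:
        """Boolean mask of voxels that carry a BED value (not excluded)."""
        return np.isfinite(self.values)


def voxel_bed(total_dose, n: int, alpha_beta: AlphaBetaRatio | float = NORMAL_TISSUE_ALPHA_BETA):
    """BED of a course total of ``total_dose`` Gy in ``n`` equal fractions.

    Closed form, vectorized over ``total_dose``:
    ``BED = D * (1 + (D/n) / (alpha/beta))``.
    """
    ab = float(_as_alpha_beta(alpha_beta))
    n = int(n)
    if n < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n}")
    d = np.asarray(total_dose, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("total_dose must be finite and >= 0 Gy")
    out = d * (1.0 + (d / n) / ab)
    return float(out) if np.isscalar(total_dose) else out


def bed_map(
    course: TreatmentCourse | DoseGrid,
    alpha_beta: AlphaBetaRatio | float = NORMAL_TISSUE_ALPHA_BETA,
    exclude: StructureMask | None = None,
    n_fractions: int | None = None,
    label: str | None = None,
) -> BEDGrid:
    """Convert a course's physical dose grid to a BED grid voxel by voxel.

    The dose grid must already be on the reference geometry (warp physical
    dose first, then convert). Voxels inside ``exclude`` (e.g. tumor) are set
    to NaN — not evaluated — and omitted from all downstream statistics.
    """
    if isinstance(course, TreatmentCourse):
        dose, n = course.dose, course.fractionation.n_fractions
        lbl = label if label is not None else course.label
    else:
        if n_fractions is None:
            raise ValueError("n_fractions is required when passing a bare DoseGrid")
        dose, n, lbl = course, n_fractions, (label or "")

    values = voxel_bed(dose.values, n, alpha_beta)
    if exclude is not None:
        if not exclude.geometry.same_as(dose.geometry):
            raise ValueError("exclusion mask geometry does not match the dose grid")
        values = values.copy()
        values[exclude.occupancy] = np.nan
    return BEDGrid(
        geometry=dose.geometry,
        values=values,
        alpha_beta=_as_alpha_beta(alpha_beta),
        source_courses=(lbl,) if lbl else (),
    )


def eqd2_from_bed(bed, alpha_beta: AlphaBetaRatio | float = NORMAL_TISSUE_ALPHA_BETA):
    """Equivalent dose in 2-Gy fractions: ``EQD2 = BED / (1 + 2/(alpha/beta))``.

    This is the standard radiobiology identity rescaling a BED to the
    conventional 2 Gy/fraction regimen.
    """
    ab = float(_as_alpha_beta(alpha_beta))
    b = np.asarray(bed, dtype=float)
    if np.any(b[np.isfinite(b)] < 0):
        raise ValueError("BED must be >= 0 Gy")
    out = b / (1.0 + 2.0 / ab)
    return float(out) if np.isscalar(bed) else out
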