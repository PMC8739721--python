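"""Cumulative dose-volume metrics per organ at risk.

Works on any grid object exposing ``geometry`` and ``values`` (composite BED,
per-course BED, or physical dose). Excluded voxels (NaN) are removed from the
structure volume before any statistic.

Conventions (each recorded in output metadata):

* ``DxCC`` — minimum dose within the hottest x cc: voxels are sorted
  descending (ties broken by voxel index), voxel volumes accumulated, and the
  value of the voxel at which the cumulative volume first reaches x cc is
  returned, with no sub-voxel interpolation.
* ``Vx`` — percent of the structure volume receiving >= x Gy (inclusive).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_io import StructureMask
from .errors import ConfigError

__all__ = [
    "DVHCurve",
    "OARMetricPanel",
    "dvh_curve",
    "d_cc",
    "v_threshold",
    "metric_panel",
    "evaluate_metric",
    "compare_constraints",
    "DEFAULT_METRIC_SPEC",
    "panel_frame",
]

#: Default metric panel per structure class: D_cc volumes (cc) and V
#: thresholds (Gy). Structures are matched to a class by name keyword.
DEFAULT_METRIC_SPEC: dict[str, dict[str, list[float]]] = {
    "plexus": {"d_cc": [0.2]},
    "cord": {"d_cc": [1.0]},
    "airway": {"d_cc": [1.0]},
    "vessel": {"d_cc": [1.0]},
    "chest_wall": {"d_cc": [30.0, 50.0]},
    "esophagus": {"d_cc": [30.0, 50.0]},
    "heart": {"d_cc": [5.0, 40.0]},
    "lung": {"v_gy": [5.0, 20.0, 35.0]},
}

_CLASS_KEYWORDS = {
    "plexus": ("plexus",),
    "cord": ("cord",),
    "airway": ("airway", "bronch", "trachea"),
    "vessel": ("vessel", "aorta", "pulmonary artery", "vena cava", "svc"),
    "chest_wall": ("chest wall", "chest_wall", "chestwall", "rib"),
    "esophagus": ("esophagus", "oesophagus"),
    "heart": ("heart",),
    "lung": ("lung",),
}

_ALLOWED_SPEC_KEYS = {"d_cc", "v_gy"}


def _structure_values(grid, mask: StructureMask) -> np.ndarray:
    """Evaluated dose values inside the mask, in voxel-index order."""
    if not mask.geometry.same_as(grid.geometry):
        raise ValueError(
            f"mask {mask.name!r} is not on the grid geometry; resample it first"
        )
    vals = np.asarray(grid.values, dtype=float)[mask.occupancy]
    return vals[np.isfinite(vals)]


@dataclass
class DVHCurve:
    """A cumulative DVH: percent of structure volume receiving >= dose."""

    name: str
    doses: np.ndarray          # sorted ascending, Gy
    volume_pct: np.ndarray     # percent of structure volume with value >= dose
    voxel_volume_cc: float

    def value_at(self, dose: float) -> float:
        """Percent of the structure volume receiving at least ``dose`` Gy."""
        if self.doses.size == 0:
            return float("nan")
        return 100.0 * float(np.count_nonzero(self.doses >= dose)) / self.doses.size


def dvh_curve(grid, mask: StructureMask) -> DVHCurve:
    """Cumulative DVH over a structure's (unexcluded) voxel multiset.

    ``curve.value_at(0) == 100`` and ``value_at(d > Dmax) == 0`` whenever the
    structure is non-empty after exclusion.
    """
    vals = _structure_values(grid, mask)
    if vals.size == 0:
        warnings.warn(f"structure {mask.name!r} empty after exclusion; DVH undefined",
                      stacklevel=2)
    doses = np.sort(vals)
    pct = 100.0 * (1.0 - np.arange(doses.size) / doses.size) if doses.size else np.array([])
    return DVHCurve(name=mask.name, doses=doses, volume_pct=pct,
                    voxel_volume_cc=mask.voxel_volume_cc)


def d_cc(grid, mask: StructureMask, volume_cc: float) -> float:
    """Minimum dose (Gy) within the hottest ``volume_cc`` of the structure."""
    if volume_cc <= 0:
        raise ValueError("volume_cc must be > 0")
    vals = _structure_values(grid, mask)
    if vals.size == 0:
        warnings.warn(f"structure {mask.name!r} empty after exclusion", stacklevel=2)
        return float("nan")
    vv = mask.voxel_volume_cc
    struct_volume = vals.size * vv
    if volume_cc > struct_volume:
        warnings.warn(
            f"requested D_{volume_cc:g}cc exceeds {mask.name!r} volume "
            f"({struct_volume:.3f} cc); returning structure minimum", stacklevel=2)
        return float(vals.min())
    # stable sort keeps voxel-index order among ties (deterministic)
    hot = np.sort(vals, kind="stable")[::-1]
    n_needed = int(np.ceil(volume_cc / vv - 1e-12))
    return float(hot[n_needed - 1])


def v_threshold(grid, mask: StructureMask, threshold_gy: float) -> float:
    """Percent of the structure volume receiving >= ``threshold_gy`` (inclusive)."""
    if threshold_gy < 0:
        raise ValueError("threshold must be >= 0 Gy")
    vals = _structure_values(grid, mask)
    if vals.size == 0:
        warnings.warn(f"structure {mask.name!r} empty after exclusion", stacklevel=2)
        return float("nan")
    return 100.0 * float(np.count_nonzero(vals >= threshold_gy)) / vals.size


# ---------------------------------------------------------------------------
# Metric panels
# ---------------------------------------------------------------------------


@dataclass
class OARMetricPanel:
    """The per-structure metric panel: Dmax, Dmean, DxCC (Gy) and Vx (%)."""

    name: str
    volume_cc: float
    dmax: float
    dmean: float
    d_cc: dict[float, float] = field(default_factory=dict)     # cc -> Gy
    v_pct: dict[float, float] = field(default_factory=dict)    # Gy -> %
    empty: bool = False

    def to_dict(self) -> dict:
        row: dict = {
            "structure": self.name,
            "volume_cc": self.volume_cc,
            "Dmax_Gy": self.dmax,
            "Dmean_Gy": self.dmean,
        }
        for cc, val in sorted(self.d_cc.items()):
            row[f"D{cc:g}cc_Gy"] = val
        for thr, val in sorted(self.v_pct.items()):
            row[f"V{thr:g}Gy_pct"] = val
        return row


def _classify(name: str) -> str | None:
    low = name.lower()
    for cls, keywords in _CLASS_KEYWORDS.items():
        if any(k in low for k in keywords):
            return cls
    return None


def _validate_spec(spec: Mapping[str, Mapping[str, Sequence[float]]]) -> None:
    for cls, entry in spec.items():
        for key in entry:
            if key not in _ALLOWED_SPEC_KEYS:
                raise ConfigError(
                    f"unknown metric keyword {key!r} for class {cls!r}; "
                    f"allowed: {sorted(_ALLOWED_SPEC_KEYS)}"
                )


def metric_panel(
    grid,
    masks: Sequence[StructureMask],
    config: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
) -> list[OARMetricPanel]:
    """Metric panels for a list of structures, in deterministic input order.

    ``config`` maps a structure class (matched by name keyword) to the D_cc
    volumes and V thresholds requested for it; it defaults to the standard
    re-irradiation panel (:data:`DEFAULT_METRIC_SPEC`). Every structure gets
    Dmax and Dmean.
    """
    spec = DEFAULT_METRIC_SPEC if config is None else config
    _validate_spec(spec)
    panels: list[OARMetricPanel] = []
    for mask in masks:
        vals = _structure_values(grid, mask)
        if vals.size == 0:
            warnings.warn(f"structure {mask.name!r} empty after exclusion; "
                          "emitting empty panel", stacklevel=2)
            panels.append(OARMetricPanel(name=mask.name, volume_cc=0.0,
                                         dmax=float("nan"), dmean=float("nan"),
                                         empty=True))
            continue
        panel = OARMetricPanel(
            name=mask.name,
            volume_cc=vals.size * mask.voxel_volume_cc,
            dmax=float(vals.max()),
            dmean=float(vals.mean()),
        )
        cls = _classify(mask.name)
        entry = spec.get(cls, {}) if cls else {}
        for cc in entry.get("d_cc", []):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                panel.d_cc[float(cc)] = d_cc(grid, mask, float(cc))
        for thr in entry.get("v_gy", []):
            panel.v_pct[float(thr)] = v_threshold(grid, mask, float(thr))
        panels.append(panel)
    return panels


def panel_frame(panels: Sequence[OARMetricPanel]) -> pd.DataFrame:
    """Panels as a tidy DataFrame (one row per structure, fixed column order)."""
    return pd.DataFrame([p.to_dict() for p in panels])


def write_panels(panels: Sequence[OARMetricPanel], csv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    df = panel_frame(panels)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps([p.to_dict() for p in panels], indent=2))


# ---------------------------------------------------------------------------
# Constraint comparison
# ---------------------------------------------------------------------------

#: Cumulative OAR metrics in this report are compared against user-supplied
#: reference values. Such references drawn from small retrospective series
#: are guidance only, not validated clinical dose constraints.
GUIDANCE_DISCLAIMER = (
    "Reference values are guidance only and must not be applied as validated "
    "clinical dose constraints; no formal statistical association between "
    "these composite-BED metrics and toxicity has been established."
)


def evaluate_metric(panel: OARMetricPanel, metric: str) -> float | None:
    """Look up a metric value (``Dmax``, ``Dmean``, ``D<x>cc``, ``V<x>Gy``) on a panel."""
    m = metric.strip()
    low = m.lower()
    if low == "dmax":
        return panel.dmax
    if low == "dmean":
        return panel.dmean
    if low.startswith("d") and low.endswith("cc"):
        try:
            cc = float(low[1:-2])
        except ValueError:
            raise ConfigError(f"unknown metric keyword {metric!r}") from None
        return panel.d_cc.get(cc)
    if low.startswith("v"):
        body = low[1:-2] if low.endswith("gy") else low[1:]
        try:
            thr = float(body)
        except ValueError:
            raise ConfigError(f"unknown metric keyword {metric!r}") from None
        return panel.v_pct.get(thr)
    raise ConfigError(f"unknown metric keyword {metric!r}")


def compare_constraints(
    panels: Sequence[OARMetricPanel],
    constraints: Sequence[Mapping],
) -> dict:
    """Compare metric panels against (structure, metric, limit) constraints.

    Each constraint maps ``structure`` (name keyword), ``metric`` (e.g.
    ``Dmax``, ``D1cc``, ``V20Gy``), ``limit`` (Gy or %), and optionally
    ``comparator`` (``le`` default, or ``ge``). Returns a report with one
    entry per constraint: the measured value, the margin (measured - limit
    for ``le``), and a flag when the constraint is exceeded. Metrics absent
    from a panel are reported as not evaluated, never as errors.
    """
    by_name = {p.name.lower(): p for p in panels}
    entries = []
    for c in constraints:
        target = str(c["structure"]).lower()
        panel = by_name.get(target)
        if panel is None:
            panel = next((p for key, p in by_name.items() if target in key), None)
        entry: dict = {
            "structure": c["structure"],
            "metric": c["metric"],
            "limit": float(c["limit"]),
            "comparator": str(c.get("comparator", "le")),
        }
        value = evaluate_metric(panel, c["metric"]) if panel is not None else None
        if value is None or not np.isfinite(value):
            entry.update(status="not-evaluated", value=None, margin=None, flagged=False)
        else:
            limit = float(c["limit"])
            if entry["comparator"] == "ge":
                margin = limit - value
            else:
                margin = value - limit
            entry.update(
                status="flagged" if margin > 0 else "pass",
                value=float(value),
                margin=float(margin),
                flagged=bool(margin > 0),
            )
        entries.append(entry)
    return {
        "disclaimer": GUIDANCE_DISCLAIMER,
        "n_constraints": len(entries),
        "n_flagged": sum(e["flagged"] for e in entries),
        "entries": entries,
    }
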