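"""Matrix overlay of the health-risk classification against land use,
plus the factory-CRI companion surface.

The integrated soil-risk class of a cell is a pure 4x4 matrix lookup
(health risk level x land-use class -> integrated level).  The default
matrix escalates risk on sensitive receptors (residential,
conservation) and relaxes it on industrial land.  The factory inherent
risk surface (IDW of per-factory CRI) is reported alongside the matrix
classification, never substituted into it; an optional escalation flag
bumps a cell's integrated class by one level where the factory surface
exceeds the extreme CRI break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import ConfigError, LandUseClass, RiskLevel
from .idw import GridSpec, IdwParams, Raster, idw_grid

# integer raster codes for land use (0 is reserved for "unset")
LAND_USE_CODES: dict[int, LandUseClass] = {
    1: LandUseClass.industrial,
    2: LandUseClass.agriculture,
    3: LandUseClass.residential,
    4: LandUseClass.conservation,
}
CODE_OF_CLASS = {lu: code for code, lu in LAND_USE_CODES.items()}

# default integrated-risk matrix: rows = health level, columns = land use
_DEFAULT_MATRIX = {
    RiskLevel.low: {
        LandUseClass.industrial: RiskLevel.low,
        LandUseClass.agriculture: RiskLevel.low,
        LandUseClass.residential: RiskLevel.moderate,
        LandUseClass.conservation: RiskLevel.high,
    },
    RiskLevel.moderate: {
        LandUseClass.industrial: RiskLevel.low,
        LandUseClass.agriculture: RiskLevel.moderate,
        LandUseClass.residential: RiskLevel.moderate,
        LandUseClass.conservation: RiskLevel.high,
    },
    RiskLevel.high: {
        LandUseClass.industrial: RiskLevel.moderate,
        LandUseClass.agriculture: RiskLevel.moderate,
        LandUseClass.residential: RiskLevel.high,
        LandUseClass.conservation: RiskLevel.extreme,
    },
    RiskLevel.extreme: {
        LandUseClass.industrial: RiskLevel.high,
        LandUseClass.agriculture: RiskLevel.high,
        LandUseClass.residential: RiskLevel.extreme,
        LandUseClass.conservation: RiskLevel.extreme,
    },
}


@dataclass(frozen=True)
class MatrixSpec:
    """Total mapping over the 16 (health level, land use) pairs."""

    table: Mapping[tuple, RiskLevel]

    def __post_init__(self):
        missing = [
            (h.name, lu.value)
            for h in RiskLevel for lu in LandUseClass
            if (h, lu) not in self.table
        ]
        if missing:
            raise ConfigError(f"matrix: missing cell(s) {missing}")

    def lookup(self, health: RiskLevel, land_use: LandUseClass) -> RiskLevel:
        return self.table[(health, land_use)]

    def column(self, land_use: LandUseClass) -> list[RiskLevel]:
        return [self.table[(h, land_use)] for h in RiskLevel]

    def is_column_monotone(self) -> bool:
        """Integrated level non-decreasing in health level for each land use."""
        for lu in LandUseClass:
            col = self.column(lu)
            if any(b < a for a, b in zip(col, col[1:])):
                return False
        return True


def default_matrix() -> MatrixSpec:
    return MatrixSpec(table={
        (h, lu): lvl
        for h, row in _DEFAULT_MATRIX.items()
        for lu, lvl in row.items()
    })


def parse_matrix(raw: Mapping) -> MatrixSpec:
    """Parse a mapping {health label: {land-use label: integrated label}}."""
    table = {}
    for h_label, row in raw.items():
        h = RiskLevel.from_label(h_label)
        for lu_label, lvl_label in row.items():
            lu = LandUseClass.from_label(lu_label)
            table[(h, lu)] = RiskLevel.from_label(lvl_label)
    return MatrixSpec(table=table)


def integrated_class(health: RiskLevel, land_use: LandUseClass,
                     m: MatrixSpec) -> RiskLevel:
    """Pure matrix lookup."""
    return m.lookup(health, land_use)


@dataclass
class IntegratedRiskMap:
    integrated: Raster  # class ranks 0..3
    factory_cri: Optional[Raster] = None  # companion surface
    provenance: dict = field(default_factory=dict)


def overlay(health_classes: Raster, land_use: Raster, m: MatrixSpec,
            factory_cri: Optional[Raster] = None,
            escalate_on_factory: bool = False,
            cri_extreme_break: float = 2.5,
            provenance: Optional[dict] = None) -> IntegratedRiskMap:
    """Cellwise matrix overlay; nodata in either input propagates.

    ``escalate_on_factory`` is an extension (off by default): where the
    companion factory-CRI surface exceeds ``cri_extreme_break``, the
    integrated class is raised one level (capped at extreme).
    """
    if not health_classes.spec.matches(land_use.spec):
        raise ValueError("grid mismatch between health-class and land-use rasters")
    if factory_cri is not None and not factory_cri.spec.matches(health_classes.spec):
        raise ValueError("grid mismatch between factory-CRI and health-class rasters")

    mask = health_classes.mask | land_use.mask
    h = health_classes.values
    lu = land_use.values

    # lookup table indexed [health rank, land-use code]
    lut = np.full((4, 5), -1, dtype=int)
    for (hl, luc), lvl in m.table.items():
        lut[hl.value, CODE_OF_CLASS[luc]] = lvl.value

    out = np.full(h.shape, health_classes.spec.nodata, dtype=float)
    valid = ~mask
    h_idx = h[valid].astype(int)
    lu_idx = lu[valid].astype(int)
    if h_idx.size:
        if h_idx.min() < 0 or h_idx.max() > 3:
            raise ValueError("health-class raster contains ranks outside 0..3")
        bad = ~np.isin(lu_idx, list(LAND_USE_CODES))
        if bad.any():
            raise ValueError(
                f"land-use raster contains unknown code(s) {sorted(set(lu_idx[bad]))}"
            )
    cell = lut[h_idx, lu_idx].astype(float)

    if escalate_on_factory and factory_cri is not None:
        hot = factory_cri.values[valid] > cri_extreme_break
        hot &= ~factory_cri.mask[valid]
        cell = np.where(hot, np.minimum(cell + 1, 3), cell)

    out[valid] = cell
    integrated = Raster(spec=health_classes.spec, values=out, mask=mask)
    return IntegratedRiskMap(
        integrated=integrated,
        factory_cri=factory_cri,
        provenance=dict(provenance or {}),
    )


def factory_surface(factories: Sequence, spec: GridSpec,
                    params: IdwParams = IdwParams(),
                    mask: Optional[np.ndarray] = None) -> Raster:
    """IDW surface of per-factory CRI on the shared grid.

    ``factories`` is a sequence of (x, y, cri) triples or objects with
    those attributes.  A single factory yields a constant surface.
    """
    rows = []
    for f in factories:
        if hasattr(f, "x"):
            rows.append((f.x, f.y, f.cri))
        else:
            rows.append(tuple(f))
    if not rows:
        raise ValueError("empty factory set")
    arr = np.asarray(rows, dtype=float)
    return idw_grid(arr[:, :2], arr[:, 2], spec, params, mask=mask)


def summarize_classes(r: Raster) -> dict:
    """Per-class cell counts and areas (cells x cell_size^2, in m2)."""
    cell_area = r.spec.cell_size ** 2
    vals = r.valid_values().astype(int)
    counts = {lvl.name: int(np.sum(vals == lvl.value)) for lvl in RiskLevel}
    return {
        "cell_counts": counts,
        "areas_m2": {k: v * cell_area for k, v in counts.items()},
        "nodata_cells": int(r.mask.sum()),
        "total_cells": int(r.values.size),
    }


def landuse_raster_from_codes(codes: np.ndarray, spec: GridSpec,
                              mask: Optional[np.ndarray] = None) -> Raster:
    """Wrap an integer code array as a land-use raster, validating codes."""
    arr = np.asarray(codes, dtype=float)
    m = np.zeros_like(arr, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    valid = arr[~m].astype(int)
    bad = ~np.isin(valid, list(LAND_USE_CODES))
    if bad.any():
        raise ConfigError(f"unknown land-use code(s) {sorted(set(valid[bad]))}")
    return Raster(spec=spec, values=arr, mask=m)
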