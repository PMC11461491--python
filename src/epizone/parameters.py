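"""Inter-zonal ET difference statistics and baseline ET descriptors.

For a zone *a* with neighbours x_1..x_n, the inter-zonal ET difference
is the mean absolute thickness contrast with its surroundings,

    d(a) = (1/n) * sum_i |ET(a) - ET(x_i)|   [µm].

Two screening parameters summarise the 41-zone difference map: the
*inferior-temporal* parameter, the mean of d over the paracentral
inferior (cI) and paracentral inferior-temporal (cTI) zones — the region
where the keratoconic cone typically sits — and the *global* parameter,
the mean of d over all 41 zones.  Both are shift-invariant (they ignore
the absolute thickness level) and scale by k when the map scales by k.

Baseline comparators (mean/SD/min/max of the zonal values and the
inferior-minus-superior mean) are provided for head-to-head ROC
comparison against the difference parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .zonemap import ETMap, ZoneGrid

__all__ = [
    "DiffMap",
    "ScreeningParameters",
    "interzonal_differences",
    "inferior_temporal_parameter",
    "global_parameter",
    "baseline_parameters",
    "compute_parameters",
]

#: Zones entering the localized (inferior-temporal) parameter.
LOCALIZED_ZONES = ("cI", "cTI")


@dataclass
class DiffMap:
    """Per-zone inter-zonal ET differences (µm, >= 0) of one ET map."""

    values: pd.Series
    source: ETMap | None = None

    def __post_init__(self) -> None:
        vals = pd.Series(self.values, dtype=float)
        if not np.isfinite(vals.to_numpy()).all() or (vals < 0).any():
            raise ValueError("difference values must be finite and >= 0")
        self.values = vals

    def __getitem__(self, alias: str) -> float:
        return float(self.values[alias])

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


@dataclass
class ScreeningParameters:
    """Screening parameters of one eye's measurement (all in µm).

    ``inferior_temporal`` and ``global_mean`` are the difference-map
    parameters; the remaining fields are the baseline comparators
    computed on the zonal thickness values themselves.
    """

    inferior_temporal: float
    global_mean: float
    mean_et: float
    sd_et: float
    min_et: float
    max_et: float
    inferior_superior: float

    FIELDS = (
        "inferior_temporal",
        "global_mean",
        "mean_et",
        "sd_et",
        "min_et",
        "max_et",
        "inferior_superior",
    )

    def as_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in self.FIELDS})


def interzonal_differences(etmap: ETMap, grid: ZoneGrid) -> DiffMap:
    """Mean absolute ET difference between each zone and its neighbours."""
    if not etmap.canonical:
        raise ValueError("map must be canonicalized before computing differences")
    v = etmap.to_numpy()
    A = grid.adjacency_matrix
    contrasts = np.abs(v[:, None] - v[None, :]) * A
    d = contrasts.sum(axis=1) / grid.degrees
    return DiffMap(pd.Series(d, index=list(grid.aliases)), source=etmap)


def inferior_temporal_parameter(diffmap: DiffMap, zones=LOCALIZED_ZONES) -> float:
    """Mean inter-zonal difference over the localized zone pair (default cI, cTI)."""
    return float(np.mean([diffmap[z] for z in zones]))


def global_parameter(diffmap: DiffMap) -> float:
    """Mean inter-zonal difference over all 41 zones."""
    return float(diffmap.values.mean())


def baseline_parameters(
    etmap: ETMap, grid: ZoneGrid, sd_ddof: int = 1
) -> dict[str, float]:
    """Baseline ET descriptors: mean, SD, min, max and inferior-superior.

    The inferior-superior value is the mean of all inferior-octant zonal
    values (rings 1-5) minus the mean of all superior-octant values; SD
    uses the sample convention (``ddof=1``) by default.
    """
    if not etmap.canonical:
        raise ValueError("map must be canonicalized")
    v = etmap.values
    inferior = v[grid.sector_aliases("I")].mean()
    superior = v[grid.sector_aliases("S")].mean()
    return {
        "mean_et": float(v.mean()),
        "sd_et": float(v.std(ddof=sd_ddof)),
        "min_et": float(v.min()),
        "max_et": float(v.max()),
        "inferior_superior": float(inferior - superior),
    }


def compute_parameters(
    etmap: ETMap, grid: ZoneGrid, localized_zones=LOCALIZED_ZONES
) -> ScreeningParameters:
    """All screening parameters of one canonical measurement."""
    d = interzonal_differences(etmap, grid)
    return ScreeningParameters(
        inferior_temporal=inferior_temporal_parameter(d, localized_zones),
        global_mean=global_parameter(d),
        **baseline_parameters(etmap, grid),
    )
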